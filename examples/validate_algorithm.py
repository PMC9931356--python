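"""Author-side validation: build the demo algorithm, lint it, and watch a
seeded content defect get caught.

The lint aggregates every static check a clinical content team would
otherwise do by hand: reference resolution, display-dependency cycles,
numeric category gaps/overlaps, severe-diagnosis referral coverage,
diagnosis reachability, and the full dosing-table sweep.
"""

from clinalg import build_fixture_algorithm, lint, serialize
from clinalg.casegen import DefectSpec, corrupt

alg = build_fixture_algorithm()
print(f"algorithm: {alg.meta.name} {alg.meta.version_id}")
print(f"  {len(alg.nodes)} questions, {len(alg.diagnoses)} diagnoses, "
      f"{len(alg.drugs)} drugs, {len(alg.dosing_rules)} dosing rules")
print(f"  canonical document: {len(serialize(alg))} bytes")

findings = lint(alg)
print(f"lint on clean content: {len(findings)} findings")

bad = corrupt(alg, DefectSpec("interval_gap"))
for f in lint(bad):
    print(f"lint on corrupted content: {f.severity} [{f.code}] {f.subject}: {f.message}")

# a gap in the MUAC categories means some measured value maps to no answer —
# exactly the kind of silent content bug that must never reach a clinic
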