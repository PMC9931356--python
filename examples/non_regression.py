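"""Non-regression testing of a clinical content change.

Raise the standard CRP cutoff from 40 to 60 mg/L and replay a fixed
seeded corpus through both versions.  The diff must touch exactly the
cases whose inputs cross the changed threshold — febrile, CRP in
[40, 60), no comorbidity (the lowered comorbidity cutoff is untouched),
and no danger sign — and nothing else.
"""

import copy

from clinalg import build_fixture_algorithm, non_regression
from clinalg.casegen import DANGER_SIGN_NODES, default_profiles, generate_cases

old = build_fixture_algorithm()
new = copy.deepcopy(old)
crp = new.nodes["crp_mgl"]
next(a for a in crp.answers if a.id == "crp_mid").hi = 60.0
next(a for a in crp.answers if a.id == "crp_high").lo = 60.0
new.meta.version_id = "demo-1.1.0"

cases = generate_cases(default_profiles(), 1000, seed=99)

self_diff = non_regression(old, old, cases)
print(f"version vs itself: {self_diff.summary()}")

diff = non_regression(old, new, cases)
print(f"cutoff 40 -> 60 mg/L: {diff.summary()}")

predicted = {
    c.id for c in cases
    if c.answers["fever"] and 40.0 <= c.answers["crp_mgl"] < 60.0
    and not c.answers["comorbidity"]
    and not any(c.answers[d] for d in DANGER_SIGN_NODES)
}
print(f"directly predicted from raw inputs: {len(predicted)} cases; "
      f"diff localized exactly: {diff.changed_case_ids == predicted}")
for d in diff.deltas[:3]:
    print(f"  {d.case_id}: -{list(d.diagnoses_removed)} "
          f"treatments -{list(d.treatments_removed)}")
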