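"""Weight-band dosing: one practical dose, then the whole-table sweep.

A dose is a multiple of the smallest dispensable increment (half
tablets, 0.5 ml) closest to the per-kg target while staying inside the
tolerated interval and the absolute cap.  The sweep verifies every
(drug, indication, formulation) cell of the tables across 2.0-25.0 kg.
"""

from clinalg import build_fixture_algorithm, compute_dose, select_rule, verify_posology
from clinalg.casegen import DefectSpec, corrupt

alg = build_fixture_algorithm()

for weight in (4.2, 10.0, 17.3):
    rule = select_rule("amoxicillin", "pneumonia", age_days=500,
                       weight_kg=weight, rules=alg.dosing_rules.values())
    dose = compute_dose(rule, alg.drugs["amoxicillin"].formulations[0], weight)
    print(f"amoxicillin at {weight:5.1f} kg -> {dose.rendering:8s} "
          f"= {dose.mg_per_dose:6.1f} mg = {dose.mg_per_kg:5.2f} mg/kg "
          f"(target {rule.target_mg_per_kg:g}, tolerated "
          f"{rule.min_mg_per_kg:g}-{rule.max_mg_per_kg:g})")

print(f"\nfull sweep on clean tables: {len(verify_posology(alg))} findings")

bad = corrupt(alg, DefectSpec("band_gap"))
findings = verify_posology(bad)
print(f"after deleting a weight band: {len(findings)} finding(s), e.g.")
print(f"  [{findings[0].code}] {findings[0].subject}: {findings[0].message}")
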