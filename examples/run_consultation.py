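"""One scripted consultation, end to end.

A 2-year-old, 10 kg, febrile with a high CRP result: staged questions,
an emergency interrupt mid-way (resumable, no effect on outputs),
severity-first proposals with explanation traces, a clinician review,
and dosed treatment proposals with a stock-out substitution.
"""

from clinalg import (
    build_fixture_algorithm,
    finalize,
    next_items,
    propose_diagnoses,
    propose_treatments,
    record_answer,
    review_diagnosis,
    start_consultation,
    trigger_emergency,
)

alg = build_fixture_algorithm()
answers = {
    "comorbidity": False, "convulsions": False, "unconscious": False,
    "unable_to_drink": False, "vomits_everything": False,
    "fever": True, "cough": False, "muac_cm": 14.0, "spo2_pct": 96.0,
    "rr_child": 30.0, "lethargic": False, "poor_feeding": False,
    "grunting": False, "chest_indrawing": False, "crp_mgl": 75.0,
}

state = start_consultation(alg, age_days=730, sex="F", weight_kg=10.0)
while True:
    items = next_items(state)
    if not items:
        break
    node = items[0]
    record_answer(state, node.id, answers[node.id])
    print(f"[{node.stage}] {node.label}: {answers[node.id]}")
    if node.id == "muac_cm":  # a convulsing child is carried in: interrupt
        guidance = trigger_emergency(state)
        print("EMERGENCY interrupt ->", "; ".join(m.label for m in guidance))

print("\nproposed diagnoses (severity-first):")
for dx, trace in propose_diagnoses(state):
    print(f"  {dx.severity_tier:9s} {dx.label}  because " + "; ".join(trace.rendered))

review_diagnosis(state, "febrile_illness", "accepted")
treatments = propose_treatments(state, stockout={"amoxicillin"})
print("\ntreatments (amoxicillin in stock-out):")
for t in treatments:
    sub = f" (substituted for {t.substituted_for})" if t.substituted_for else ""
    print(f"  {t.drug_id}{sub}: {t.dose.rendering} = {t.dose.mg_per_kg:.1f} mg/kg, "
          f"{t.dose.frequency_per_day}x/day for {t.dose.duration_days} days")

record = finalize(state)
print(f"\nexport: version {record['algorithm_version']}, "
      f"referral recommended: {record['referral_recommended']}, "
      f"{len(record['answers'])} answers, "
      f"{len(record['emergency_log'])} emergency interrupt(s)")
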