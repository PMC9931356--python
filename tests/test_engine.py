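"""Consultation executor: staging, gating, proposals, review, treatments."""

import numpy as np
import pytest

from clinalg.engine import (
    EngineError,
    PatientCase,
    finalize,
    next_items,
    propose_diagnoses,
    propose_treatments,
    record_answer,
    referral_recommended,
    review_diagnosis,
    run_case,
    start_consultation,
    start_for_case,
    trigger_emergency,
)


def drive(alg, case, until_stage=None):
    """Answer items in presentation order, optionally stopping before a stage."""
    state = start_for_case(alg, case)
    while True:
        items = next_items(state)
        if not items:
            break
        if until_stage is not None and items[0].stage == until_stage:
            break
        record_answer(state, items[0].id, case.answers[items[0].id])
    return state


def base_case(**overrides):
    answers = {
        "comorbidity": False,
        "convulsions": False,
        "unconscious": False,
        "unable_to_drink": False,
        "vomits_everything": False,
        "fever": False,
        "cough": False,
        "muac_cm": 14.0,
        "spo2_pct": 97.0,
        "rr_infant": 35.0,
        "rr_child": 25.0,
        "lethargic": False,
        "poor_feeding": False,
        "grunting": False,
        "chest_indrawing": False,
        "crp_mgl": 5.0,
    }
    answers.update(overrides.pop("answers", {}))
    kw = dict(id="t", age_days=730, sex="F", weight_kg=10.0, answers=answers)
    kw.update(overrides)
    return PatientCase(**kw)


def test_age_outside_algorithm_range_is_rejected(alg):
    with pytest.raises(EngineError, match="age"):
        start_consultation(alg, age_days=16 * 365, sex="M", weight_kg=40.0)


def test_young_infant_branch_becomes_askable(alg):
    """A 30-day-old is routed to the infant respiratory-rate thresholds."""
    case = base_case(age_days=30, weight_kg=3.5)
    state = drive(alg, case, until_stage="signs")
    asked = set(state.answered)
    assert "rr_infant" in asked
    assert "rr_child" not in asked


def test_danger_signs_precede_other_clinical_questions(alg):
    state = start_consultation(alg, 400, "F", 9.0)
    record_answer(state, "comorbidity", False)
    items = next_items(state)
    assert {n.stage for n in items} == {"first_look"}
    assert all(n.emergency_relevant for n in items)


def test_gated_question_appears_only_after_its_trigger(alg):
    case = base_case(answers={"fever": True})
    state = drive(alg, case, until_stage="tests")
    items = next_items(state)
    assert [n.id for n in items] == ["crp_mgl"]
    # without fever the CRP test is never shown
    state2 = drive(alg, base_case())
    assert "crp_mgl" not in state2.answered


@pytest.mark.parametrize(
    "node,value,answer",
    [
        ("muac_cm", 12.0, "muac_low"),
        ("muac_cm", 12.5, "muac_ok"),
        ("spo2_pct", 89.0, "spo2_low"),
        ("spo2_pct", 90.0, "spo2_ok"),
    ],
)
def test_numeric_values_categorize_to_threshold_answers(alg, node, value, answer):
    case = base_case(answers={node: value})
    state = drive(alg, case)
    assert state.answered[node].answer_id == answer


def test_out_of_range_numeric_value_rejected(alg):
    state = drive(alg, base_case(), until_stage="vitals")
    with pytest.raises(Exception, match="admissible"):
        record_answer(state, "muac_cm", 45.0)


def test_estimated_value_warns_and_requires_estimable(alg):
    state = drive(alg, base_case(), until_stage="vitals")
    record_answer(state, "muac_cm", 14.0, estimated=True)
    assert any("sub-optimal" in w for w in state.warnings)
    with pytest.raises(EngineError, match="estimated"):
        record_answer(state, "spo2_pct", 97.0, estimated=True)


def test_answer_recording_is_idempotent_on_same_value(alg):
    state = drive(alg, base_case(), until_stage="vitals")
    record_answer(state, "muac_cm", 14.0)
    record_answer(state, "muac_cm", 14.0)  # no-op
    with pytest.raises(EngineError, match="answered"):
        record_answer(state, "muac_cm", 15.0)


def test_emergency_interrupt_any_time_and_resumable(alg):
    fresh = start_consultation(alg, 400, "F", 9.0)
    guidance = trigger_emergency(fresh)
    assert guidance and all(m.emergency_guidance for m in guidance)

    case = base_case()
    state = drive(alg, case, until_stage="vitals")
    before = [n.id for n in next_items(state)]
    trigger_emergency(state)
    trigger_emergency(state)
    assert [n.id for n in next_items(state)] == before
    assert len(state.emergency_log) == 2
    assert (
        state.emergency_log[0]["at_order_index"]
        <= state.emergency_log[1]["at_order_index"]
    )


def test_emergency_interrupt_does_not_change_outputs(alg):
    case = base_case(answers={"fever": True, "crp_mgl": 80.0})
    plain = run_case(alg, case)
    state = drive(alg, case, until_stage="signs")
    trigger_emergency(state)
    while True:
        items = next_items(state)
        if not items:
            break
        record_answer(state, items[0].id, case.answers[items[0].id])
    proposals = propose_diagnoses(state)
    assert tuple(d.id for d, _ in proposals) == plain.diagnoses
    assert referral_recommended(state) == plain.referral


def test_danger_sign_tops_with_referral(alg):
    case = base_case(answers={"convulsions": True, "fever": True})
    state = drive(alg, case)
    proposals = propose_diagnoses(state)
    top, trace = proposals[0]
    assert top.severity_tier in ("emergency", "severe")
    assert any(
        alg.managements[m].kind == "referral" for m in top.managements
    )
    assert ("convulsions", "yes") in [
        (a.node_id, a.answer_id) for a, holds in trace.atoms if holds
    ]


def test_crp_branch_without_severe_signs_gets_antibiotic(alg):
    case = base_case(answers={"fever": True, "crp_mgl": 60.0})
    out = run_case(alg, case)
    assert "crp_bacterial" in out.diagnoses
    assert "amoxicillin" in out.treatments
    assert not out.referral


def test_comorbidity_lowers_the_crp_cutoff(alg):
    """CRP 25 mg/L triggers the bacterial branch only with comorbidity —
    the raised pre-test probability justifies a lower marker cutoff."""
    plain = run_case(alg, base_case(answers={"fever": True, "crp_mgl": 25.0}))
    comorbid = run_case(
        alg, base_case(answers={"fever": True, "crp_mgl": 25.0, "comorbidity": True})
    )
    assert "crp_bacterial" not in plain.diagnoses
    assert "crp_bacterial" in comorbid.diagnoses


def test_no_condition_true_falls_back_to_supportive_care(alg):
    out = run_case(alg, base_case())
    assert out.diagnoses == ("home_care",)
    assert out.treatments == ()


def test_composite_impression_needs_two_of_four_signs(alg):
    one = run_case(alg, base_case(answers={"lethargic": True}))
    two = run_case(alg, base_case(answers={"lethargic": True, "grunting": True}))
    assert "severe_clinical_impression" not in one.diagnoses
    assert "severe_clinical_impression" in two.diagnoses
    assert two.referral


def test_refused_mild_diagnosis_drops_its_drug(alg):
    case = base_case(answers={"fever": True})
    state = drive(alg, case)
    propose_diagnoses(state)
    review_diagnosis(state, "febrile_illness", "refused", "parent declines")
    treatments = propose_treatments(state)
    assert "paracetamol" not in {t.drug_id for t in treatments}


def test_refusing_referral_diagnosis_keeps_warning_in_export(alg):
    case = base_case(answers={"spo2_pct": 85.0})
    state = drive(alg, case)
    propose_diagnoses(state)
    review_diagnosis(state, "hypoxaemia", "refused", "disagree")
    review_diagnosis(state, "hypoxaemia", "refused", "disagree")  # idempotent
    record = finalize(state)
    assert any("referral remains recommended" in w for w in record["warnings"])


def test_review_of_non_proposed_diagnosis_rejected(alg):
    state = drive(alg, base_case())
    propose_diagnoses(state)
    with pytest.raises(EngineError, match="not proposed"):
        review_diagnosis(state, "pneumonia", "accepted")


def test_stockout_substitutes_flagged_alternative(alg):
    case = base_case(answers={"cough": True, "rr_child": 55.0})
    state = drive(alg, case)
    propose_diagnoses(state)
    treatments = propose_treatments(state, stockout={"amoxicillin"})
    tx = {t.drug_id: t for t in treatments}
    assert "cotrimoxazole" in tx
    assert tx["cotrimoxazole"].substituted_for == "amoxicillin"
    assert tx["cotrimoxazole"].dose.within_bounds


def test_duplicate_drug_dispensed_once_for_most_severe_indication(alg):
    case = base_case(
        answers={"cough": True, "rr_child": 55.0, "fever": True, "crp_mgl": 90.0}
    )
    state = drive(alg, case)
    proposals = propose_diagnoses(state)
    assert {"pneumonia", "crp_bacterial"} <= {d.id for d, _ in proposals}
    treatments = propose_treatments(state)
    amox = [t for t in treatments if t.drug_id == "amoxicillin"]
    assert len(amox) == 1
    assert amox[0].indication == "pneumonia"  # higher authoring priority


def test_all_refused_yields_empty_treatments(alg):
    case = base_case(answers={"fever": True})
    state = drive(alg, case)
    proposals = propose_diagnoses(state)
    for d, _ in proposals:
        review_diagnosis(state, d.id, "refused", "n/a")
    assert propose_treatments(state) == []


def test_finalized_export_is_complete_and_immutable(alg):
    case = base_case(answers={"fever": True}, estimated={"muac_cm"})
    state = start_for_case(alg, case)
    while True:
        items = next_items(state)
        if not items:
            break
        n = items[0]
        record_answer(state, n.id, case.answers[n.id], estimated=n.id in case.estimated)
    propose_diagnoses(state)
    record = finalize(state)
    assert record["algorithm_version"] == alg.meta.version_id
    assert any(a["estimated"] for a in record["answers"])
    assert any("sub-optimal" in w for w in record["warnings"])
    assert record["referral_recommended"] is False
    with pytest.raises(EngineError, match="finalized"):
        trigger_emergency(state)


def test_finalize_before_diagnosis_phase_rejected(alg):
    state = start_consultation(alg, 400, "M", 9.0)
    with pytest.raises(EngineError, match="finalize"):
        finalize(state)


def test_explanation_traces_replay_to_true(alg, cases_small):
    """Every explanation, replayed alone against its diagnosis condition,
    suffices to satisfy it."""
    from clinalg.conditions import Atom, Tri, tri_of

    for case in cases_small[:80]:
        state = drive(alg, case)
        for dx, trace in propose_diagnoses(state):
            sub = dict(trace.atoms)
            v = dx.condition.evaluate(lambda n, a: tri_of(sub.get(Atom(n, a))))
            assert v is Tri.TRUE


def test_answer_order_never_changes_outputs(alg, cases_small):
    rng = np.random.default_rng(42)
    for case in cases_small[:60]:
        ref = run_case(alg, case)
        assert ref.error is None
        for _ in range(3):
            alt = run_case(alg, case, answer_order_rng=rng)
            assert alt.diagnoses == ref.diagnoses
            assert alt.treatments == ref.treatments
            assert alt.referral == ref.referral


def test_adding_a_danger_sign_never_lowers_top_severity(alg, cases_small):
    from clinalg.model import severity_rank

    for case in cases_small[:60]:
        ref = run_case(alg, case)
        aug = PatientCase(
            id=case.id, age_days=case.age_days, sex=case.sex,
            weight_kg=case.weight_kg,
            answers={**case.answers, "convulsions": True},
            estimated=set(case.estimated), label=case.label,
        )
        out = run_case(alg, aug)
        rank_ref = severity_rank(alg.diagnoses[ref.diagnoses[0]].severity_tier)
        rank_aug = severity_rank(alg.diagnoses[out.diagnoses[0]].severity_tier)
        assert rank_aug <= rank_ref
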