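"""Lint, reachability, corpus replay, non-regression, unit checks."""

import copy
import itertools

import pytest

from clinalg.casegen import DefectSpec, build_fixture_algorithm, corrupt
from clinalg.conditions import Tri, atom, tri_of
from clinalg.engine import PatientCase
from clinalg.model import Diagnosis
from clinalg.qa import (
    Expectation,
    diagnosis_reachable,
    lint,
    non_regression,
    run_corpus,
    unit_check,
)

DEFECT_TO_CODE = {
    "cycle": "cycle",
    "unreachable_diagnosis": "unreachable_diagnosis",
    "dangling_reference": "dangling_reference",
    "interval_gap": "interval_gap",
    "interval_overlap": "interval_overlap",
    "dose_out_of_bounds": "dose_out_of_bounds",
    "band_gap": "band_gap",
}


def test_clean_fixture_lints_empty(alg):
    assert lint(alg) == []


@pytest.mark.parametrize("defect", sorted(DEFECT_TO_CODE))
def test_each_seeded_defect_yields_exactly_its_finding_class(alg, defect):
    findings = lint(corrupt(alg, DefectSpec(defect)))
    assert findings, defect
    assert {f.code for f in findings} == {DEFECT_TO_CODE[defect]}


def test_severe_diagnosis_stripped_of_referral_is_flagged(alg):
    bad = copy.deepcopy(alg)
    bad.diagnoses["hypoxaemia"].managements = ["follow_up_2d"]
    findings = lint(bad)
    assert any(
        f.code == "severe_without_referral" and f.subject == "hypoxaemia"
        for f in findings
    )


def brute_force_reachable(alg, dx):
    """Independent satisfiability oracle: full product over the closure's
    answer choices (plus 'unanswered' for gated nodes), keeping only
    gating-consistent assignments."""
    want = set(dx.condition.node_ids())
    frontier = list(want)
    while frontier:
        node = alg.nodes[frontier.pop()]
        if node.display_condition is not None:
            for dep in node.display_condition.node_ids():
                if dep not in want:
                    want.add(dep)
                    frontier.append(dep)
    ids = sorted(want)
    choice_sets = []
    for nid in ids:
        n = alg.nodes[nid]
        opts = [a.id for a in n.answers]
        if n.display_condition is not None:
            opts.append(None)
        choice_sets.append(opts)
    for combo in itertools.product(*choice_sets):
        values = dict(zip(ids, combo))

        def look(node_id, answer_id):
            if node_id not in values:
                return Tri.UNKNOWN
            v = values[node_id]
            return tri_of(v == answer_id if v is not None else False)

        consistent = True
        for nid in ids:
            n = alg.nodes[nid]
            if n.display_condition is None:
                continue
            gate = n.display_condition.evaluate(look)
            if (values[nid] is None) != (gate is not Tri.TRUE):
                consistent = False
                break
        if consistent and dx.condition.evaluate(look) is Tri.TRUE:
            return True
    return False


def test_reachability_agrees_with_brute_force(alg):
    for dx in alg.diagnoses.values():
        assert diagnosis_reachable(alg, dx) is brute_force_reachable(alg, dx)
    bad = corrupt(alg, DefectSpec("unreachable_diagnosis"))
    dx = bad.diagnoses["crp_bacterial"]
    assert diagnosis_reachable(bad, dx) is False
    assert brute_force_reachable(bad, dx) is False


def test_run_corpus_is_deterministic_and_error_free(alg, cases_small):
    t1 = run_corpus(alg, cases_small)
    t2 = run_corpus(alg, cases_small)
    assert len(t1) == len(cases_small)
    assert (t1.error == "").all()
    assert t1.to_csv(index=False) == t2.to_csv(index=False)


def test_case_outside_age_range_fails_alone(alg, cases_small):
    stray = PatientCase(
        id="too-old", age_days=16 * 365, sex="M", weight_kg=45.0,
        answers=dict(cases_small[0].answers), label="well_child",
    )
    table = run_corpus(alg, list(cases_small[:10]) + [stray])
    errs = table[table.error != ""]
    assert list(errs.case_id) == ["too-old"]
    assert (table[table.case_id != "too-old"].error == "").all()


def test_non_regression_of_identical_content_is_empty(alg, cases_small):
    diff = non_regression(alg, alg, cases_small)
    assert diff.empty
    assert diff.summary()["cases_changed"] == 0


def raise_crp_cutoff(alg, new_cut=60.0):
    new = copy.deepcopy(alg)
    crp = new.nodes["crp_mgl"]
    mid = next(a for a in crp.answers if a.id == "crp_mid")
    high = next(a for a in crp.answers if a.id == "crp_high")
    mid.hi = new_cut
    high.lo = new_cut
    new.meta.version_id = "demo-1.1.0"
    return new


def test_cutoff_change_diffs_exactly_the_predicted_cases(alg, cases_small):
    """Raising the standard CRP cutoff from 40 to 60 mg/L must change
    exactly the cases computed directly from raw inputs: febrile,
    CRP in [40, 60), no comorbidity (lowered cutoff unaffected), and no
    danger sign (severity-first exclusion)."""
    new = raise_crp_cutoff(alg)
    diff = non_regression(alg, new, cases_small)
    danger = ("convulsions", "unconscious", "unable_to_drink", "vomits_everything")
    predicted = {
        c.id
        for c in cases_small
        if c.answers["fever"]
        and 40.0 <= c.answers["crp_mgl"] < 60.0
        and not c.answers["comorbidity"]
        and not any(c.answers[d] for d in danger)
    }
    assert diff.changed_case_ids == predicted
    for d in diff.deltas:
        assert d.diagnoses_removed == ("crp_bacterial",)
        assert not d.items_added and not d.items_removed
        assert not d.referral_changed


def test_added_mild_diagnosis_never_touches_referral(alg, cases_small):
    new = copy.deepcopy(alg)
    new.diagnoses["cough_advice"] = Diagnosis(
        id="cough_advice", label="Cough advice", severity_tier="mild",
        condition=atom("cough", "yes"), managements=["supportive_advice"],
        excludes=["home_care"],
    )
    diff = non_regression(alg, new, cases_small)
    assert diff.summary()["referral_changed"] == 0
    for d in diff.deltas:
        assert "cough_advice" in d.diagnoses_added


def authored_expectations():
    return [
        (
            PatientCase(
                id="exp-danger", age_days=500, sex="F", weight_kg=10.0,
                answers={
                    "comorbidity": False, "convulsions": True,
                    "unconscious": False, "unable_to_drink": False,
                    "vomits_everything": False, "fever": True, "cough": False,
                    "muac_cm": 14.0, "spo2_pct": 96.0, "rr_child": 30.0,
                    "lethargic": False, "poor_feeding": False,
                    "grunting": False, "chest_indrawing": False, "crp_mgl": 10.0,
                },
            ),
            Expectation(
                "exp-danger",
                frozenset({"very_severe_disease"}),
                expected_referral=True,
                expected_drugs=frozenset(),
            ),
        ),
        (
            PatientCase(
                id="exp-crp", age_days=900, sex="M", weight_kg=12.0,
                answers={
                    "comorbidity": False, "convulsions": False,
                    "unconscious": False, "unable_to_drink": False,
                    "vomits_everything": False, "fever": True, "cough": False,
                    "muac_cm": 14.0, "spo2_pct": 96.0, "rr_child": 30.0,
                    "lethargic": False, "poor_feeding": False,
                    "grunting": False, "chest_indrawing": False, "crp_mgl": 75.0,
                },
            ),
            Expectation(
                "exp-crp",
                frozenset({"crp_bacterial", "febrile_illness"}),
                expected_referral=False,
                expected_drugs=frozenset({"amoxicillin", "paracetamol"}),
            ),
        ),
    ]


def test_authored_expectations_all_pass(alg):
    pairs = authored_expectations()
    results = unit_check(alg, [c for c, _ in pairs], [e for _, e in pairs])
    assert all(r.passed for r in results), [r.detail for r in results]


def test_wrong_expectation_fails_naming_the_case(alg):
    pairs = authored_expectations()
    wrong = Expectation(
        "exp-danger", frozenset({"home_care"}), expected_referral=False
    )
    results = unit_check(alg, [c for c, _ in pairs], [wrong])
    assert len(results) == 1
    assert not results[0].passed
    assert results[0].case_id == "exp-danger"
    assert "diagnoses" in results[0].detail
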