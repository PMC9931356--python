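"""Synthetic fixture factory: demo algorithm, labelled cases, seeded defects.

Real national algorithm content is maintained externally by health
authorities and is not shipped here; this module provides a small but
structurally faithful *demo* pediatric outpatient algorithm and a seeded
generator of labelled synthetic patient cases, so the whole toolchain
(validation, execution, dosing, QA) can be exercised end to end.

The demo algorithm is severity-first: IMCI-style danger signs and a
composite "2 of 4 signs" clinical-impression item feed emergency/severe
referral diagnoses; a fever complaint gates a CRP-style inflammation
test with a standard cutoff (40 mg/L) and a lowered comorbidity cutoff
(20 mg/L); a respiratory branch uses age-dependent fast-breathing
thresholds.  The MUAC < 12.5 cm and SpO2 < 90% thresholds are the
standard clinical cutoffs; every other number (CRP cutoffs, respiratory
rates, dosing figures) is invented demo content.

``corrupt`` injects exactly one defect of a requested class into a copy
of an algorithm — the seeded ground truth for the QA lint tests.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .conditions import all_of, any_of, at_least, atom
from .engine import PatientCase
from .model import (
    AlgorithmMeta,
    Answer,
    ClinicalAlgorithm,
    Diagnosis,
    DosingRule,
    DrugDefinition,
    Formulation,
    Management,
    Node,
    TreatmentSpec,
    assign_terminology,
)

DEFECT_CLASSES = (
    "cycle",
    "unreachable_diagnosis",
    "dangling_reference",
    "interval_gap",
    "interval_overlap",
    "dose_out_of_bounds",
    "band_gap",
)

DANGER_SIGN_NODES = (
    "convulsions",
    "unconscious",
    "unable_to_drink",
    "vomits_everything",
)

IMPRESSION_SIGN_NODES = ("lethargic", "poor_feeding", "grunting", "chest_indrawing")


def _bool_answers() -> list[Answer]:
    return [Answer("yes", "yes"), Answer("no", "no")]


def build_fixture_algorithm() -> ClinicalAlgorithm:
    """The deterministic demo algorithm (identical on every call)."""
    stages = ["registration", "first_look", "complaints", "vitals", "signs", "tests"]
    nodes: dict[str, Node] = {}

    def add(node: Node) -> None:
        nodes[node.id] = node

    add(
        Node(
            id="age_band", stage="registration", kind="calculated",
            label="Age band", answer_type="numeric", unit="days",
            admissible_lo=0, admissible_hi=7300,
            answers=[
                Answer("lt_2m", "< 2 months", 0, 60),
                Answer("m2_to_12m", "2-12 months", 60, 365),
                Answer("ge_12m", ">= 12 months", 365, 7300),
            ],
            auto_from="age_days",
        )
    )
    add(
        Node(
            id="comorbidity", stage="registration", kind="background",
            label="Chronic comorbidity", answer_type="boolean",
            answers=_bool_answers(),
            help="e.g. sickle cell disease, HIV, prior severe malnutrition",
        )
    )
    for nid, label in (
        ("convulsions", "Convulsions during this illness"),
        ("unconscious", "Unconscious or unresponsive"),
        ("unable_to_drink", "Unable to drink or breastfeed"),
        ("vomits_everything", "Vomits everything"),
    ):
        add(
            Node(
                id=nid, stage="first_look", kind="sign", label=label,
                answer_type="boolean", answers=_bool_answers(),
                referral_triggering=True, emergency_relevant=True,
            )
        )
    add(
        Node(
            id="fever", stage="complaints", kind="complaint",
            label="Fever (reported or measured)", answer_type="boolean",
            answers=_bool_answers(),
        )
    )
    add(
        Node(
            id="cough", stage="complaints", kind="complaint",
            label="Cough or difficult breathing", answer_type="boolean",
            answers=_bool_answers(),
        )
    )
    add(
        Node(
            id="muac_cm", stage="vitals", kind="measurement",
            label="Mid-upper arm circumference", answer_type="numeric",
            unit="cm", admissible_lo=6.0, admissible_hi=30.0,
            answers=[
                Answer("muac_low", "< 12.5 cm", 6.0, 12.5),
                Answer("muac_ok", ">= 12.5 cm", 12.5, 30.0),
            ],
            referral_triggering=True, estimable=True,
        )
    )
    add(
        Node(
            id="spo2_pct", stage="vitals", kind="measurement",
            label="Oxygen saturation", answer_type="numeric",
            unit="%", admissible_lo=50.0, admissible_hi=100.0,
            answers=[
                Answer("spo2_low", "< 90%", 50.0, 90.0),
                Answer("spo2_ok", ">= 90%", 90.0, 100.0),
            ],
            referral_triggering=True,
        )
    )
    add(
        Node(
            id="rr_infant", stage="vitals", kind="measurement",
            label="Respiratory rate (infant)", answer_type="numeric",
            unit="breaths/min", admissible_lo=10.0, admissible_hi=120.0,
            answers=[
                Answer("normal", "< 50/min", 10.0, 50.0),
                Answer("fast", ">= 50/min", 50.0, 120.0),
            ],
            display_condition=any_of(
                atom("age_band", "lt_2m"), atom("age_band", "m2_to_12m")
            ),
            estimable=True,
        )
    )
    add(
        Node(
            id="rr_child", stage="vitals", kind="measurement",
            label="Respiratory rate (child)", answer_type="numeric",
            unit="breaths/min", admissible_lo=10.0, admissible_hi=120.0,
            answers=[
                Answer("normal", "< 40/min", 10.0, 40.0),
                Answer("fast", ">= 40/min", 40.0, 120.0),
            ],
            display_condition=atom("age_band", "ge_12m"),
            estimable=True,
        )
    )
    for nid, label in (
        ("lethargic", "Lethargic or drowsy"),
        ("poor_feeding", "Feeding poorly"),
        ("grunting", "Grunting or noisy breathing"),
        ("chest_indrawing", "Lower chest wall indrawing"),
    ):
        add(
            Node(
                id=nid, stage="signs", kind="sign", label=label,
                answer_type="boolean", answers=_bool_answers(),
            )
        )
    add(
        Node(
            id="crp_mgl", stage="tests", kind="test",
            label="CRP point-of-care test", answer_type="numeric",
            unit="mg/L", admissible_lo=0.0, admissible_hi=200.0,
            answers=[
                Answer("crp_low", "< 20 mg/L", 0.0, 20.0),
                Answer("crp_mid", "20-39 mg/L", 20.0, 40.0),
                Answer("crp_high", ">= 40 mg/L", 40.0, 200.0),
            ],
            display_condition=atom("fever", "yes"),
        )
    )

    managements = {
        m.id: m
        for m in [
            Management("refer_urgent", "Refer urgently to hospital", "referral"),
            Management(
                "emergency_abc",
                "Stabilise airway, breathing, circulation",
                "pre_referral_treatment",
                emergency_guidance=True,
            ),
            Management(
                "emergency_position",
                "Recovery position; oxygen if available",
                "counselling",
                emergency_guidance=True,
            ),
            Management("supportive_advice", "Home care and supportive advice", "counselling"),
            Management("follow_up_2d", "Follow-up visit in 2 days", "follow_up"),
        ]
    }

    danger_any = any_of(*(atom(n, "yes") for n in DANGER_SIGN_NODES))
    diagnoses: dict[str, Diagnosis] = {}

    def add_dx(dx: Diagnosis) -> None:
        diagnoses[dx.id] = dx

    add_dx(
        Diagnosis(
            id="very_severe_disease",
            label="Very severe disease (danger sign)",
            severity_tier="emergency",
            condition=danger_any,
            managements=["refer_urgent", "emergency_abc"],
            excludes=["pneumonia", "crp_bacterial", "febrile_illness", "home_care"],
        )
    )
    add_dx(
        Diagnosis(
            id="severe_clinical_impression",
            label="Severe illness (clinical impression, 2 of 4 signs)",
            severity_tier="severe",
            condition=at_least(2, *(atom(n, "yes") for n in IMPRESSION_SIGN_NODES)),
            managements=["refer_urgent"],
            excludes=["home_care"],
        )
    )
    add_dx(
        Diagnosis(
            id="hypoxaemia",
            label="Hypoxaemia (SpO2 < 90%)",
            severity_tier="severe",
            condition=atom("spo2_pct", "spo2_low"),
            managements=["refer_urgent", "emergency_position"],
            excludes=["home_care"],
        )
    )
    add_dx(
        Diagnosis(
            id="severe_malnutrition_risk",
            label="Acute malnutrition risk (MUAC < 12.5 cm)",
            severity_tier="severe",
            condition=atom("muac_cm", "muac_low"),
            managements=["refer_urgent"],
            excludes=["home_care"],
        )
    )
    add_dx(
        Diagnosis(
            id="pneumonia",
            label="Pneumonia (fast breathing for age)",
            severity_tier="moderate",
            condition=all_of(
                atom("cough", "yes"),
                any_of(atom("rr_infant", "fast"), atom("rr_child", "fast")),
            ),
            managements=["follow_up_2d"],
            treatments=[TreatmentSpec("amoxicillin", ["cotrimoxazole"])],
            excludes=["home_care"],
        )
    )
    add_dx(
        Diagnosis(
            id="crp_bacterial",
            label="Bacterial infection likely (CRP branch)",
            severity_tier="moderate",
            condition=all_of(
                atom("fever", "yes"),
                any_of(
                    atom("crp_mgl", "crp_high"),
                    all_of(
                        atom("comorbidity", "yes"),
                        any_of(atom("crp_mgl", "crp_mid"), atom("crp_mgl", "crp_high")),
                    ),
                ),
            ),
            managements=["follow_up_2d"],
            treatments=[TreatmentSpec("amoxicillin", ["cotrimoxazole"])],
            excludes=["home_care"],
        )
    )
    add_dx(
        Diagnosis(
            id="febrile_illness",
            label="Fever without bacterial indication",
            severity_tier="mild",
            condition=atom("fever", "yes"),
            managements=["supportive_advice"],
            treatments=[TreatmentSpec("paracetamol")],
            excludes=["home_care"],
        )
    )
    add_dx(
        Diagnosis(
            id="home_care",
            label="No specific condition — supportive home care",
            severity_tier="mild",
            condition=any_of(atom("fever", "yes"), atom("fever", "no")),
            managements=["supportive_advice"],
        )
    )

    drugs = {
        d.id: d
        for d in [
            DrugDefinition(
                "amoxicillin", "Amoxicillin",
                [Formulation("suspension", strength_mg=50.0, increment=0.5)],
            ),
            DrugDefinition(
                "cotrimoxazole", "Cotrimoxazole",
                [Formulation("suspension", strength_mg=48.0, increment=0.5)],
            ),
            DrugDefinition(
                "paracetamol", "Paracetamol",
                [Formulation("syrup", strength_mg=24.0, increment=0.5)],
            ),
        ]
    }

    def bands(rule_prefix, drug, indication, target, lo, hi, cap, freq, days):
        out = {}
        for i, (wlo, whi) in enumerate(((2.0, 10.0), (10.0, 25.0)), start=1):
            rid = f"{rule_prefix}-w{i}"
            out[rid] = DosingRule(
                id=rid, drug_id=drug, indication=indication,
                age_lo_days=0, age_hi_days=5475,
                weight_lo_kg=wlo, weight_hi_kg=whi,
                target_mg_per_kg=target, min_mg_per_kg=lo, max_mg_per_kg=hi,
                max_mg_per_dose=cap, frequency_per_day=freq, duration_days=days,
            )
        return out

    dosing_rules: dict[str, DosingRule] = {}
    dosing_rules.update(bands("amox-pneu", "amoxicillin", "pneumonia", 25, 20, 30, 1000, 2, 5))
    dosing_rules.update(bands("amox-crp", "amoxicillin", "crp_bacterial", 25, 20, 30, 1000, 2, 5))
    dosing_rules.update(bands("cotri-pneu", "cotrimoxazole", "pneumonia", 24, 18, 30, 960, 2, 5))
    dosing_rules.update(bands("cotri-crp", "cotrimoxazole", "crp_bacterial", 24, 18, 30, 960, 2, 5))
    dosing_rules.update(bands("para-fev", "paracetamol", "febrile_illness", 15, 10, 20, 500, 4, 3))

    alg = ClinicalAlgorithm(
        meta=AlgorithmMeta(
            name="mini-pediatric-outpatient-demo",
            country="demo",
            version_id="demo-1.0.0",
            age_min_days=0,
            age_max_days=5475,  # under 15 years
        ),
        stages=stages,
        nodes=nodes,
        diagnoses=diagnoses,
        managements=managements,
        drugs=drugs,
        dosing_rules=dosing_rules,
    )
    assign_terminology(alg)
    return alg


# -- condition profiles -----------------------------------------------------


@dataclass(frozen=True)
class NumericSpec:
    """Generative distribution for one numeric predictor.

    ``dist`` is "normal" (mean, sd) or "lognormal" (mu, sigma on the log
    scale).  Draws are truncated (by rejection) to the node's admissible
    range, and :meth:`design_mean` returns the mean of that truncated
    distribution in closed form, so generator fidelity can be tested
    against exactly what the generator samples.
    """

    dist: str
    p1: float
    p2: float

    def sample(self, rng: np.random.Generator, lo: float, hi: float) -> float:
        for _ in range(200):
            x = (
                rng.normal(self.p1, self.p2)
                if self.dist == "normal"
                else rng.lognormal(self.p1, self.p2)
            )
            if lo <= x < hi:
                return float(x)
        return float(min(max(x, lo), np.nextafter(hi, lo)))

    def design_mean(self, lo: float, hi: float) -> float:
        if self.dist == "normal":
            a = (lo - self.p1) / self.p2
            b = (hi - self.p1) / self.p2
            return float(stats.truncnorm(a, b, loc=self.p1, scale=self.p2).mean())
        mu, s = self.p1, self.p2
        lo_ = max(lo, 1e-12)
        z = lambda x: (np.log(x) - mu) / s
        mass = stats.norm.cdf(z(hi)) - stats.norm.cdf(z(lo_))
        partial = np.exp(mu + s**2 / 2) * (
            stats.norm.cdf(z(hi) - s) - stats.norm.cdf(z(lo_) - s)
        )
        return float(partial / mass)

    def design_sd(self, lo: float, hi: float, n_mc: int = 200_000, seed: int = 0) -> float:
        # second moment of the truncated law, by a large seeded draw
        rng = np.random.default_rng(seed)
        xs = np.array([self.sample(rng, lo, hi) for _ in range(n_mc)])
        return float(xs.std(ddof=1))


@dataclass(frozen=True)
class ConditionProfile:
    """Generative description of one labelled condition."""

    label: str
    weight: float
    bool_probs: dict[str, float] = field(default_factory=dict)
    numeric_specs: dict[str, NumericSpec] = field(default_factory=dict)
    age_lo_days: int = 61
    age_hi_days: int = 1825
    estimated_prob: float = 0.0
    default_bool_p: float = 0.01


# invented demo epidemiology: prevalences skewed toward non-severe children,
# matching outpatient settings where few non-severe children need antibiotics
def default_profiles() -> list[ConditionProfile]:
    base_numeric = {
        "muac_cm": NumericSpec("normal", 14.5, 1.0),
        "spo2_pct": NumericSpec("normal", 98.0, 1.2),
        "rr_infant": NumericSpec("normal", 38.0, 5.0),
        "rr_child": NumericSpec("normal", 26.0, 4.0),
        "crp_mgl": NumericSpec("lognormal", 1.6, 0.6),
    }

    def prof(label, weight, bools, numerics, **kw):
        merged = dict(base_numeric)
        merged.update(numerics)
        return ConditionProfile(
            label=label, weight=weight, bool_probs=bools,
            numeric_specs=merged, **kw,
        )

    return [
        prof(
            "well_child", 0.40,
            {"fever": 0.05, "cough": 0.10, "comorbidity": 0.05},
            {},
            estimated_prob=0.05,
        ),
        prof(
            "viral_urti", 0.30,
            {"fever": 0.95, "cough": 0.70, "comorbidity": 0.05},
            {
                "crp_mgl": NumericSpec("lognormal", 2.0, 0.5),
                "spo2_pct": NumericSpec("normal", 97.0, 1.5),
                "rr_infant": NumericSpec("normal", 42.0, 5.0),
                "rr_child": NumericSpec("normal", 30.0, 5.0),
            },
            estimated_prob=0.10,
        ),
        prof(
            "pneumonia", 0.10,
            {
                "fever": 0.90, "cough": 0.95, "comorbidity": 0.10,
                "lethargic": 0.15, "poor_feeding": 0.15,
                "grunting": 0.15, "chest_indrawing": 0.15,
                **{n: 0.02 for n in DANGER_SIGN_NODES},
            },
            {
                "crp_mgl": NumericSpec("lognormal", 3.6, 0.5),
                "spo2_pct": NumericSpec("normal", 94.0, 2.5),
                "rr_infant": NumericSpec("normal", 58.0, 6.0),
                "rr_child": NumericSpec("normal", 48.0, 6.0),
            },
            estimated_prob=0.10,
        ),
        prof(
            "severe_malnutrition_risk", 0.08,
            {"fever": 0.30, "cough": 0.15, "comorbidity": 0.20, "poor_feeding": 0.30},
            {"muac_cm": NumericSpec("normal", 11.5, 0.7)},
        ),
        prof(
            "hypoxaemia", 0.05,
            {
                "fever": 0.70, "cough": 0.80, "comorbidity": 0.10,
                "grunting": 0.30, "chest_indrawing": 0.30,
            },
            {
                "spo2_pct": NumericSpec("normal", 86.0, 3.0),
                "rr_infant": NumericSpec("normal", 60.0, 7.0),
                "rr_child": NumericSpec("normal", 50.0, 7.0),
                "crp_mgl": NumericSpec("lognormal", 3.0, 0.6),
            },
        ),
        prof(
            "very_severe_disease", 0.07,
            {
                "fever": 0.95, "cough": 0.40, "comorbidity": 0.15,
                **{n: 0.45 for n in DANGER_SIGN_NODES},
                **{n: 0.40 for n in IMPRESSION_SIGN_NODES},
            },
            {
                "crp_mgl": NumericSpec("lognormal", 4.2, 0.5),
                "spo2_pct": NumericSpec("normal", 92.0, 3.5),
                "rr_infant": NumericSpec("normal", 55.0, 8.0),
                "rr_child": NumericSpec("normal", 45.0, 8.0),
            },
        ),
    ]


def _weight_for_age(age_days: float, rng: np.random.Generator) -> float:
    months = age_days / 30.44
    if months <= 12:
        median = 3.3 + 0.5 * months
    else:
        median = 9.3 + 0.2 * (months - 12)
    w = rng.normal(median, 0.10 * median)
    return float(min(max(w, 2.5), 24.5))


def generate_cases(
    profiles: Sequence[ConditionProfile],
    n: int,
    seed: int,
    alg: Optional[ClinicalAlgorithm] = None,
) -> list[PatientCase]:
    """Draw ``n`` labelled cases, fully reproducible under ``seed``.

    Each case samples a condition by prevalence weight, then every
    predictor from that condition's generative spec; every non-derived
    node of the algorithm receives a value, so any questioning path the
    engine takes is answerable.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    weights = np.array([p.weight for p in profiles], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(f"prevalence weights sum to {weights.sum()}, not 1")
    if alg is None:
        alg = build_fixture_algorithm()
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(profiles), size=n, p=weights)
    cases: list[PatientCase] = []
    askable_nodes = [nd for nd in alg.nodes.values() if nd.auto_from is None]
    for i in range(n):
        p = profiles[int(labels[i])]
        age = int(rng.integers(p.age_lo_days, p.age_hi_days))
        sex = "F" if rng.random() < 0.5 else "M"
        weight = _weight_for_age(age, rng)
        answers: dict[str, object] = {}
        estimated: set[str] = set()
        for node in askable_nodes:
            if node.answer_type == "boolean":
                pr = p.bool_probs.get(node.id, p.default_bool_p)
                answers[node.id] = bool(rng.random() < pr)
            elif node.answer_type == "numeric":
                spec = p.numeric_specs.get(node.id)
                if spec is None:
                    raise ValueError(
                        f"profile {p.label!r} lacks a spec for numeric node {node.id!r}"
                    )
                v = round(spec.sample(rng, node.admissible_lo, node.admissible_hi), 2)
                # rounding must not escape the half-open admissible range
                if v >= node.admissible_hi:
                    v = node.admissible_hi - 0.01
                if v < node.admissible_lo:
                    v = node.admissible_lo
                answers[node.id] = v
            else:
                answers[node.id] = node.answers[0].id
            if node.estimable and rng.random() < p.estimated_prob:
                estimated.add(node.id)
        cases.append(
            PatientCase(
                id=f"case-{i:05d}", age_days=age, sex=sex, weight_kg=round(weight, 2),
                answers=answers, estimated=estimated, label=p.label,
            )
        )
    return cases


# -- seeded defect injection ------------------------------------------------


@dataclass(frozen=True)
class DefectSpec:
    defect_class: str
    target: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.defect_class not in DEFECT_CLASSES:
            raise ValueError(f"unknown defect class {self.defect_class!r}")


def corrupt(alg: ClinicalAlgorithm, defect: DefectSpec) -> ClinicalAlgorithm:
    """A minimally-modified copy exhibiting exactly the requested defect."""
    bad = copy.deepcopy(alg)
    cls = defect.defect_class
    if cls == "cycle":
        a = defect.target or "grunting"
        b = "chest_indrawing" if a != "chest_indrawing" else "grunting"
        if a not in bad.nodes or b not in bad.nodes:
            raise ValueError(f"cycle target {a!r} not applicable")
        bad.nodes[a].display_condition = atom(b, "yes")
        bad.nodes[b].display_condition = atom(a, "yes")
    elif cls == "unreachable_diagnosis":
        t = defect.target or "crp_bacterial"
        if t not in bad.diagnoses:
            raise ValueError(f"unreachable target {t!r} not a diagnosis")
        # two different answers of one question can never hold together
        bad.diagnoses[t].condition = all_of(
            atom("crp_mgl", "crp_low"), atom("crp_mgl", "crp_high")
        )
    elif cls == "dangling_reference":
        t = defect.target or "febrile_illness"
        if t not in bad.diagnoses:
            raise ValueError(f"dangling target {t!r} not a diagnosis")
        bad.diagnoses[t].condition = atom("ghost_node", "yes")
    elif cls == "interval_gap":
        t = defect.target or "muac_cm"
        node = bad.nodes.get(t)
        if node is None or node.answer_type != "numeric" or len(node.answers) < 2:
            raise ValueError(f"interval target {t!r} not applicable")
        node.answers[-1].lo = node.answers[-1].lo + 0.5
    elif cls == "interval_overlap":
        t = defect.target or "muac_cm"
        node = bad.nodes.get(t)
        if node is None or node.answer_type != "numeric" or len(node.answers) < 2:
            raise ValueError(f"interval target {t!r} not applicable")
        node.answers[-1].lo = node.answers[-1].lo - 0.5
    elif cls == "dose_out_of_bounds":
        t = defect.target or "para-fev-w1"
        rule = bad.dosing_rules.get(t)
        if rule is None:
            raise ValueError(f"dosing target {t!r} not a rule")
        # a tolerated window far below any dispensable increment
        rule.target_mg_per_kg = 2.0
        rule.min_mg_per_kg = 2.0
        rule.max_mg_per_kg = 2.0
    elif cls == "band_gap":
        t = defect.target or "amox-pneu-w2"
        if t not in bad.dosing_rules:
            raise ValueError(f"band target {t!r} not a rule")
        del bad.dosing_rules[t]
    return bad
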