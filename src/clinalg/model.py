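"""Domain types for a decision-tree clinical algorithm.

A :class:`ClinicalAlgorithm` is the machine-executable yet human-auditable
form of a clinical guideline: staged questions (nodes) with threshold-coded
answers, Boolean display conditions, severity-tiered diagnoses with
managements and weight-band drug dosing tables, and a stable terminology
code for every node and diagnosis.

Construction is lenient; :func:`validate_algorithm` reports *every*
violated invariant at once (an algorithm author needs the full defect
list, not the first failure), and :func:`clinalg.io.build_algorithm`
refuses to return an algorithm with error-severity findings.

Conventions: ages in days, weights in kg, temperatures in °C.  Numeric
answer categories are half-open intervals ``[lo, hi)`` so that a printed
cutoff like "MUAC < 12.5 cm" is the upper bound of the lower category.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .conditions import AtLeast, Condition

SEVERITY_TIERS = ("emergency", "severe", "moderate", "mild")

NODE_KINDS = (
    "complaint",
    "symptom",
    "sign",
    "measurement",
    "test",
    "background",
    "calculated",
)

MANAGEMENT_KINDS = ("referral", "pre_referral_treatment", "counselling", "follow_up")

FORMULATION_FORMS = ("tablet", "dispersible_tablet", "syrup", "suspension", "injection")


def severity_rank(tier: str) -> int:
    """Lower rank = more severe (emergency first)."""
    return SEVERITY_TIERS.index(tier)


@dataclass
class Answer:
    """One admissible answer to a node.

    For numeric nodes the answer is a half-open interval ``[lo, hi)`` over
    the measured value; for boolean/categorical nodes ``lo``/``hi`` are
    None and the answer is selected directly.
    """

    id: str
    label: str
    lo: Optional[float] = None
    hi: Optional[float] = None

    def contains(self, value: float) -> bool:
        assert self.lo is not None and self.hi is not None
        return self.lo <= value < self.hi


@dataclass
class Node:
    id: str
    stage: str
    kind: str
    label: str
    answer_type: str  # "boolean" | "categorical" | "numeric"
    answers: list[Answer]
    unit: Optional[str] = None
    admissible_lo: Optional[float] = None
    admissible_hi: Optional[float] = None
    display_condition: Optional[Condition] = None
    referral_triggering: bool = False
    estimable: bool = False
    emergency_relevant: bool = False
    help: Optional[str] = None
    # For background nodes whose value the engine derives from demographics
    # ("age_days" or "weight_kg") instead of asking the clinician.
    auto_from: Optional[str] = None

    def answer_ids(self) -> set[str]:
        return {a.id for a in self.answers}

    def categorize(self, value: float) -> Answer:
        """Map a numeric measurement to its threshold-interval answer."""
        if self.answer_type != "numeric":
            raise ValueError(f"node {self.id} is not numeric")
        if not (self.admissible_lo <= value < self.admissible_hi):
            raise ValueError(
                f"value {value} outside admissible range "
                f"[{self.admissible_lo}, {self.admissible_hi}) of node {self.id}"
            )
        for a in self.answers:
            if a.contains(value):
                return a
        raise ValueError(
            f"no answer interval of node {self.id} covers {value} "
            "(interval gap — run validation)"
        )


@dataclass
class Management:
    id: str
    label: str
    kind: str
    # Emergency guidance items are surfaced by the engine's emergency
    # interrupt regardless of consultation stage.
    emergency_guidance: bool = False


@dataclass
class TreatmentSpec:
    """First-line drug plus ordered alternatives for a diagnosis."""

    drug_id: str
    alternative_drug_ids: list[str] = field(default_factory=list)


@dataclass
class Diagnosis:
    id: str
    label: str
    severity_tier: str
    condition: Condition
    managements: list[str] = field(default_factory=list)
    treatments: list[TreatmentSpec] = field(default_factory=list)
    excludes: list[str] = field(default_factory=list)


@dataclass
class Formulation:
    form: str
    strength_mg: float  # mg per tablet, or mg per ml for liquids
    increment: float  # smallest dispensable multiple (tablets or ml)

    @property
    def is_liquid(self) -> bool:
        return self.form in ("syrup", "suspension", "injection")

    @property
    def step_mg(self) -> float:
        return self.strength_mg * self.increment


@dataclass
class DrugDefinition:
    id: str
    name: str
    formulations: list[Formulation]


@dataclass
class DosingRule:
    """Per-kg posology for one (drug, indication) over an age×weight band."""

    id: str
    drug_id: str
    indication: str  # diagnosis id
    age_lo_days: float
    age_hi_days: float
    weight_lo_kg: float
    weight_hi_kg: float
    target_mg_per_kg: float
    min_mg_per_kg: float
    max_mg_per_kg: float
    max_mg_per_dose: float
    frequency_per_day: int
    duration_days: int

    def covers(self, age_days: float, weight_kg: float) -> bool:
        return (
            self.age_lo_days <= age_days < self.age_hi_days
            and self.weight_lo_kg <= weight_kg < self.weight_hi_kg
        )


@dataclass
class AlgorithmMeta:
    name: str
    country: str
    version_id: str
    age_min_days: int
    age_max_days: int


@dataclass
class ClinicalAlgorithm:
    meta: AlgorithmMeta
    stages: list[str]
    nodes: dict[str, Node]
    diagnoses: dict[str, Diagnosis]
    managements: dict[str, Management]
    drugs: dict[str, DrugDefinition]
    dosing_rules: dict[str, DosingRule]
    terminology: dict[str, str] = field(default_factory=dict)

    def node_order(self, node_id: str) -> int:
        """Authoring order index of a node."""
        return list(self.nodes).index(node_id)

    def diagnosis_order(self, dx_id: str) -> int:
        return list(self.diagnoses).index(dx_id)


@dataclass(frozen=True)
class Finding:
    """One static-validation / lint finding."""

    severity: str  # "error" | "warning"
    code: str
    subject: str
    message: str


FINDING_CODES = (
    "duplicate_id",
    "dangling_reference",
    "cycle",
    "interval_gap",
    "interval_overlap",
    "interval_out_of_range",
    "bad_age_range",
    "bad_enum",
    "bad_condition",
    "severe_without_referral",
    "referral_node_unused",
    "self_exclusion",
    "bad_dosing_rule",
    "band_overlap",
    "band_gap",
    "dose_out_of_bounds",
    "unreachable_diagnosis",
    "unreachability_heuristic",
)


def assign_terminology(alg: ClinicalAlgorithm) -> None:
    """Auto-assign stable namespaced codes to nodes/diagnoses lacking one.

    The code is a deterministic digest of (algorithm name, version, id), so
    rebuilding the same document always yields identical assignments.
    """
    for ident in list(alg.nodes) + list(alg.diagnoses):
        if ident not in alg.terminology:
            h = hashlib.sha1(
                f"{alg.meta.name}:{alg.meta.version_id}:{ident}".encode()
            ).hexdigest()
            alg.terminology[ident] = f"CA-{h[:8].upper()}"


def _check_condition_refs(
    cond: Condition, alg: ClinicalAlgorithm, subject: str, out: list[Finding]
) -> None:
    for a in cond.atoms():
        node = alg.nodes.get(a.node_id)
        if node is None:
            out.append(
                Finding(
                    "error",
                    "dangling_reference",
                    subject,
                    f"condition references unknown node {a.node_id!r}",
                )
            )
        elif a.answer_id not in node.answer_ids():
            out.append(
                Finding(
                    "error",
                    "dangling_reference",
                    subject,
                    f"condition references unknown answer "
                    f"{a.node_id!r}/{a.answer_id!r}",
                )
            )


def _walk_at_least(cond: Condition) -> Iterable[AtLeast]:
    from .conditions import And, Not, Or

    if isinstance(cond, AtLeast):
        yield cond
    elif isinstance(cond, (And, Or)):
        for t in cond.terms:
            yield from _walk_at_least(t)
    elif isinstance(cond, Not):
        yield from _walk_at_least(cond.term)


def validate_algorithm(alg: ClinicalAlgorithm) -> list[Finding]:
    """All structural invariant violations, never just the first.

    Checks id uniqueness and reference resolution, acyclicity of display
    dependencies, the age range, numeric answer-interval partitions
    (gap / overlap / out-of-range), severe-diagnosis referral coverage,
    referral-triggering node usage, exclusion irreflexivity, and dosing
    rule well-formedness (including weight-band overlap).  Dynamic checks
    (unreachable diagnoses, dosing sweeps) live in :mod:`clinalg.qa`.
    """
    out: list[Finding] = []
    m = alg.meta
    if not m.age_min_days < m.age_max_days:
        out.append(
            Finding(
                "error",
                "bad_age_range",
                m.name,
                f"age range [{m.age_min_days}, {m.age_max_days}) is empty",
            )
        )

    # id uniqueness across registries
    seen: dict[str, str] = {}
    for kind, reg in (
        ("node", alg.nodes),
        ("diagnosis", alg.diagnoses),
        ("management", alg.managements),
        ("drug", alg.drugs),
        ("dosing_rule", alg.dosing_rules),
    ):
        for ident in reg:
            if ident in seen:
                out.append(
                    Finding(
                        "error",
                        "duplicate_id",
                        ident,
                        f"id used by both {seen[ident]} and {kind}",
                    )
                )
            else:
                seen[ident] = kind

    # nodes
    for node in alg.nodes.values():
        if node.stage not in alg.stages:
            out.append(
                Finding("error", "bad_enum", node.id, f"unknown stage {node.stage!r}")
            )
        if node.kind not in NODE_KINDS:
            out.append(
                Finding("error", "bad_enum", node.id, f"unknown kind {node.kind!r}")
            )
        if node.answer_type == "numeric":
            lo, hi = node.admissible_lo, node.admissible_hi
            if lo is None or hi is None or not lo < hi:
                out.append(
                    Finding(
                        "error",
                        "bad_enum",
                        node.id,
                        "numeric node needs admissible range lo < hi",
                    )
                )
            else:
                ivals = sorted(
                    (a for a in node.answers),
                    key=lambda a: (a.lo if a.lo is not None else float("-inf")),
                )
                for a in ivals:
                    if a.lo is None or a.hi is None:
                        out.append(
                            Finding(
                                "error",
                                "bad_enum",
                                node.id,
                                f"numeric answer {a.id!r} lacks interval bounds",
                            )
                        )
                    elif a.lo < lo or a.hi > hi:
                        out.append(
                            Finding(
                                "error",
                                "interval_out_of_range",
                                node.id,
                                f"answer {a.id!r} interval [{a.lo}, {a.hi}) exceeds "
                                f"admissible [{lo}, {hi})",
                            )
                        )
                bounded = [a for a in ivals if a.lo is not None and a.hi is not None]
                cursor = lo
                for a in bounded:
                    if a.lo > cursor:
                        out.append(
                            Finding(
                                "error",
                                "interval_gap",
                                node.id,
                                f"no answer covers [{cursor}, {a.lo}) of node {node.id}",
                            )
                        )
                    elif a.lo < cursor:
                        out.append(
                            Finding(
                                "error",
                                "interval_overlap",
                                node.id,
                                f"answer {a.id!r} overlaps previous interval at "
                                f"[{a.lo}, {min(cursor, a.hi)})",
                            )
                        )
                    cursor = max(cursor, a.hi)
                if bounded and cursor < hi:
                    out.append(
                        Finding(
                            "error",
                            "interval_gap",
                            node.id,
                            f"no answer covers [{cursor}, {hi}) of node {node.id}",
                        )
                    )
        if node.display_condition is not None:
            _check_condition_refs(node.display_condition, alg, node.id, out)

    # display-dependency acyclicity (graph module reports the cycle path)
    from .graph import find_cycle

    cycle = find_cycle(alg)
    if cycle:
        out.append(
            Finding(
                "error",
                "cycle",
                cycle[0],
                "display-condition dependency cycle: " + " -> ".join(cycle),
            )
        )

    # diagnoses
    referral_mgmt_ids = {
        m_.id for m_ in alg.managements.values() if m_.kind == "referral"
    }
    used_in_severe: set[str] = set()
    for dx in alg.diagnoses.values():
        if dx.severity_tier not in SEVERITY_TIERS:
            out.append(
                Finding(
                    "error", "bad_enum", dx.id, f"unknown tier {dx.severity_tier!r}"
                )
            )
        _check_condition_refs(dx.condition, alg, dx.id, out)
        for al in _walk_at_least(dx.condition):
            if al.k > len(al.items):
                out.append(
                    Finding(
                        "error",
                        "bad_condition",
                        dx.id,
                        f"AT_LEAST k={al.k} exceeds {len(al.items)} atoms",
                    )
                )
        for mid in dx.managements:
            if mid not in alg.managements:
                out.append(
                    Finding(
                        "error",
                        "dangling_reference",
                        dx.id,
                        f"unknown management {mid!r}",
                    )
                )
        for t in dx.treatments:
            for did in [t.drug_id] + list(t.alternative_drug_ids):
                if did not in alg.drugs:
                    out.append(
                        Finding(
                            "error",
                            "dangling_reference",
                            dx.id,
                            f"unknown drug {did!r}",
                        )
                    )
        for ex in dx.excludes:
            if ex == dx.id:
                out.append(
                    Finding("error", "self_exclusion", dx.id, "diagnosis excludes itself")
                )
            elif ex not in alg.diagnoses:
                out.append(
                    Finding(
                        "error",
                        "dangling_reference",
                        dx.id,
                        f"excludes unknown diagnosis {ex!r}",
                    )
                )
        if dx.severity_tier in ("emergency", "severe"):
            if not any(mid in referral_mgmt_ids for mid in dx.managements):
                out.append(
                    Finding(
                        "error",
                        "severe_without_referral",
                        dx.id,
                        f"{dx.severity_tier} diagnosis lacks a referral management",
                    )
                )
            used_in_severe |= dx.condition.node_ids()

    for node in alg.nodes.values():
        if node.referral_triggering and node.id not in used_in_severe:
            out.append(
                Finding(
                    "error",
                    "referral_node_unused",
                    node.id,
                    "referral-triggering node appears in no severe/emergency "
                    "diagnosis condition",
                )
            )

    # dosing rules
    for rule in alg.dosing_rules.values():
        if rule.drug_id not in alg.drugs:
            out.append(
                Finding(
                    "error",
                    "dangling_reference",
                    rule.id,
                    f"dosing rule references unknown drug {rule.drug_id!r}",
                )
            )
        if rule.indication not in alg.diagnoses:
            out.append(
                Finding(
                    "error",
                    "dangling_reference",
                    rule.id,
                    f"dosing rule references unknown diagnosis {rule.indication!r}",
                )
            )
        if not (rule.min_mg_per_kg <= rule.target_mg_per_kg <= rule.max_mg_per_kg):
            out.append(
                Finding(
                    "error",
                    "bad_dosing_rule",
                    rule.id,
                    "tolerated interval must satisfy min <= target <= max",
                )
            )
        if rule.age_lo_days >= rule.age_hi_days or rule.weight_lo_kg >= rule.weight_hi_kg:
            out.append(
                Finding("error", "bad_dosing_rule", rule.id, "empty age/weight band")
            )
    rules = list(alg.dosing_rules.values())
    for i, r1 in enumerate(rules):
        for r2 in rules[i + 1 :]:
            if r1.drug_id == r2.drug_id and r1.indication == r2.indication:
                if (
                    r1.age_lo_days < r2.age_hi_days
                    and r2.age_lo_days < r1.age_hi_days
                    and r1.weight_lo_kg < r2.weight_hi_kg
                    and r2.weight_lo_kg < r1.weight_hi_kg
                ):
                    out.append(
                        Finding(
                            "error",
                            "band_overlap",
                            r1.id,
                            f"band overlaps rule {r2.id} for "
                            f"({r1.drug_id}, {r1.indication})",
                        )
                    )

    for drug in alg.drugs.values():
        if not drug.formulations:
            out.append(
                Finding("error", "bad_enum", drug.id, "drug has no formulations")
            )
        for f in drug.formulations:
            if f.form not in FORMULATION_FORMS or f.strength_mg <= 0 or f.increment <= 0:
                out.append(
                    Finding(
                        "error", "bad_enum", drug.id, f"malformed formulation {f!r}"
                    )
                )

    out.sort(key=lambda f: (f.code, f.subject, f.message))
    return out
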