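"""Deterministic consultation executor.

Drives one patient encounter through a validated algorithm: staged
questioning gated by three-valued display conditions, an emergency
interrupt available at any point, severity-first diagnosis proposal with
minimal explanation traces, clinician accept/refuse review, and
treatment proposal with stock-out alternatives and weight-band dosing.

Unanswered atoms are *unknown* while questioning (a question only
becomes askable once its display condition is definitely true); at
diagnosis time, a question whose display condition resolved false was
legitimately never asked and its atoms count as false — skipped branches
cannot contribute to a diagnosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .conditions import Atom, Tri, minimal_support
from .dosing import DoseResult, compute_dose, select_rule
from .graph import topological_index
from .model import ClinicalAlgorithm, Diagnosis, Management, Node, severity_rank

AGE_SANE_MAX_DAYS = 20 * 365


class EngineError(RuntimeError):
    pass


@dataclass
class PatientCase:
    """One (possibly synthetic) patient: demographics, raw answers, label.

    ``answers`` maps node id to the raw entered value (bool for boolean
    nodes, number for numeric nodes, answer id for categorical ones).
    ``estimated`` lists measurement nodes whose value was estimated rather
    than measured.  ``label`` is the gold condition for labelled synthetic
    cases, None for real ones.
    """

    id: str
    age_days: int
    sex: str
    weight_kg: float
    answers: dict[str, object] = field(default_factory=dict)
    estimated: set[str] = field(default_factory=set)
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.age_days < AGE_SANE_MAX_DAYS):
            raise ValueError(f"age {self.age_days} d outside [0, {AGE_SANE_MAX_DAYS})")
        if self.weight_kg <= 0:
            raise ValueError("weight must be positive")


@dataclass
class RecordedAnswer:
    value: object
    answer_id: str
    estimated: bool
    order_index: int


@dataclass
class ExplanationTrace:
    """Minimal set of (node, answer) facts that made a diagnosis true."""

    diagnosis_id: str
    atoms: list[tuple[Atom, bool]]
    rendered: list[str]


@dataclass
class Review:
    decision: str  # "accepted" | "refused"
    reason: str = ""


@dataclass
class TreatmentProposal:
    drug_id: str
    indication: str
    dose: Optional[DoseResult]
    substituted_for: Optional[str] = None  # first-line drug if an alternative was used
    note: str = ""


@dataclass
class ConsultationState:
    algorithm: ClinicalAlgorithm
    age_days: int
    sex: str
    weight_kg: float
    answered: dict[str, RecordedAnswer] = field(default_factory=dict)
    stage_idx: int = 0
    emergency_log: list[dict] = field(default_factory=list)
    proposed: Optional[list[tuple[Diagnosis, ExplanationTrace]]] = None
    reviewed: dict[str, Review] = field(default_factory=dict)
    proposed_treatments: Optional[list[TreatmentProposal]] = None
    warnings: list[str] = field(default_factory=list)
    finalized: bool = False
    _order_counter: int = 0
    _topo: dict[str, int] = field(default_factory=dict)

    # -- three-valued atom lookups -----------------------------------------

    def _ask_lookup(self, node_id: str, answer_id: str) -> Tri:
        rec = self.answered.get(node_id)
        if rec is None:
            return Tri.UNKNOWN
        return Tri.TRUE if rec.answer_id == answer_id else Tri.FALSE

    def _resolve_lookup(self, node_id: str, answer_id: str, _stack=None) -> Tri:
        """Diagnosis-time lookup: gated-off unanswered nodes resolve false."""
        rec = self.answered.get(node_id)
        if rec is not None:
            return Tri.TRUE if rec.answer_id == answer_id else Tri.FALSE
        node = self.algorithm.nodes.get(node_id)
        if node is None:
            return Tri.UNKNOWN
        if node.display_condition is None:
            return Tri.UNKNOWN  # askable but never answered: unresolved
        gate = node.display_condition.evaluate(
            lambda n, a: self._resolve_lookup(n, a)
        )
        if gate is Tri.FALSE:
            return Tri.FALSE  # legitimately never asked
        return Tri.UNKNOWN


def start_consultation(
    alg: ClinicalAlgorithm, age_days: int, sex: str, weight_kg: float
) -> ConsultationState:
    """Open an encounter; fails if the patient is outside the algorithm's
    applicable age range (wrong algorithm selected)."""
    if not (alg.meta.age_min_days <= age_days < alg.meta.age_max_days):
        raise EngineError(
            f"age {age_days} d outside algorithm range "
            f"[{alg.meta.age_min_days}, {alg.meta.age_max_days}) d"
        )
    state = ConsultationState(
        algorithm=alg, age_days=age_days, sex=sex, weight_kg=weight_kg
    )
    state._topo = topological_index(alg)
    # background nodes derived from demographics are recorded up front
    for node in alg.nodes.values():
        if node.auto_from is not None:
            value = age_days if node.auto_from == "age_days" else weight_kg
            answer = node.categorize(float(value))
            state.answered[node.id] = RecordedAnswer(
                value=value, answer_id=answer.id, estimated=False,
                order_index=state._order_counter,
            )
            state._order_counter += 1
    return state


def start_for_case(alg: ClinicalAlgorithm, case: PatientCase) -> ConsultationState:
    return start_consultation(alg, case.age_days, case.sex, case.weight_kg)


def _askable_in_stage(state: ConsultationState, stage: str) -> list[Node]:
    alg = state.algorithm
    out = []
    for node in alg.nodes.values():
        if node.stage != stage or node.id in state.answered or node.auto_from:
            continue
        if node.display_condition is None:
            out.append(node)
        elif node.display_condition.evaluate(state._ask_lookup) is Tri.TRUE:
            out.append(node)
    out.sort(key=lambda n: (state._topo[n.id], alg.node_order(n.id)))
    return out


def next_items(state: ConsultationState) -> list[Node]:
    """Askable nodes of the current stage, advancing stages when exhausted.

    Order: stage order, then topological order of the display-dependency
    graph, then authoring order.  Returns [] once every stage is
    exhausted — the consultation is then in the diagnosis phase.
    """
    if state.finalized:
        raise EngineError("consultation is finalized")
    stages = state.algorithm.stages
    while state.stage_idx < len(stages):
        items = _askable_in_stage(state, stages[state.stage_idx])
        if items:
            return items
        state.stage_idx += 1
    return []


def record_answer(
    state: ConsultationState,
    node_id: str,
    value: object,
    estimated: bool = False,
) -> ConsultationState:
    """Record one answer; numeric values are mapped to their threshold
    answer; estimated values are flagged with a sub-optimal warning."""
    if state.finalized:
        raise EngineError("consultation is finalized")
    alg = state.algorithm
    node = alg.nodes.get(node_id)
    if node is None:
        raise EngineError(f"unknown node {node_id!r}")
    prior = state.answered.get(node_id)
    if prior is not None:
        if prior.value == value:
            return state  # idempotent re-entry of the same value
        raise EngineError(f"node {node_id!r} already answered differently")
    askable_ids = {n.id for n in next_items(state)}
    if node_id not in askable_ids:
        raise EngineError(f"node {node_id!r} is not currently askable")
    if estimated and not node.estimable:
        raise EngineError(f"node {node_id!r} does not allow estimated values")

    if node.answer_type == "numeric":
        answer = node.categorize(float(value))  # raises if out of range
    elif node.answer_type == "boolean":
        if isinstance(value, bool):
            aid = "yes" if value else "no"
        else:
            aid = str(value)
        matches = [a for a in node.answers if a.id == aid]
        if not matches:
            raise EngineError(f"value {value!r} not an answer of {node_id!r}")
        answer = matches[0]
    else:
        matches = [a for a in node.answers if a.id == str(value)]
        if not matches:
            raise EngineError(f"value {value!r} not an answer of {node_id!r}")
        answer = matches[0]

    state.answered[node_id] = RecordedAnswer(
        value=value, answer_id=answer.id, estimated=estimated,
        order_index=state._order_counter,
    )
    state._order_counter += 1
    if estimated:
        state.warnings.append(
            f"estimated value for '{node.label}' — sub-optimal, measurement preferred"
        )
    return state


def trigger_emergency(state: ConsultationState) -> list[Management]:
    """Emergency interrupt: immediately return the algorithm's emergency
    guidance, at any point, leaving the consultation resumable."""
    if state.finalized:
        raise EngineError("consultation is finalized")
    guidance = [
        m for m in state.algorithm.managements.values() if m.emergency_guidance
    ]
    state.emergency_log.append(
        {"at_order_index": state._order_counter, "n_answered": len(state.answered)}
    )
    return guidance


def _resolved_value(state: ConsultationState, a: Atom) -> bool | None:
    v = state._resolve_lookup(a.node_id, a.answer_id)
    if v is Tri.TRUE:
        return True
    if v is Tri.FALSE:
        return False
    return None


def propose_diagnoses(
    state: ConsultationState,
) -> list[tuple[Diagnosis, ExplanationTrace]]:
    """Severity-first diagnosis proposal with explanation traces.

    All stages must be traversed and every atom referenced by a diagnosis
    condition resolved (answered, or its display gate false).  Active
    diagnoses suppress those listed in their ``excludes``; the remainder
    are ordered emergency > severe > moderate > mild, ties by authoring
    order.
    """
    if next_items(state):
        raise EngineError("stages not fully traversed")
    alg = state.algorithm
    unresolved: set[str] = set()
    truths: dict[str, bool] = {}
    for dx in alg.diagnoses.values():
        v = dx.condition.evaluate(state._resolve_lookup)
        if v is Tri.UNKNOWN:
            for a in dx.condition.atoms():
                if state._resolve_lookup(a.node_id, a.answer_id) is Tri.UNKNOWN:
                    unresolved.add(a.node_id)
        truths[dx.id] = v is Tri.TRUE
    if unresolved:
        raise EngineError(
            "unresolved atoms at diagnosis time: " + ", ".join(sorted(unresolved))
        )
    ordered = sorted(
        (dx for dx in alg.diagnoses.values() if truths[dx.id]),
        key=lambda d: (severity_rank(d.severity_tier), alg.diagnosis_order(d.id)),
    )
    suppressed: set[str] = set()
    kept: list[Diagnosis] = []
    for dx in ordered:
        if dx.id in suppressed:
            continue
        kept.append(dx)
        suppressed.update(dx.excludes)
    result = []
    for dx in kept:
        support = minimal_support(dx.condition, lambda a: _resolved_value(state, a))
        rendered = []
        for a, holds in support:
            node = alg.nodes[a.node_id]
            ans = next(x for x in node.answers if x.id == a.answer_id)
            rendered.append(
                f"{node.label} = {ans.label}" if holds else f"{node.label} ≠ {ans.label}"
            )
        result.append((dx, ExplanationTrace(dx.id, support, rendered)))
    state.proposed = result
    return result


def review_diagnosis(
    state: ConsultationState, diagnosis_id: str, decision: str, reason: str = ""
) -> ConsultationState:
    if state.finalized:
        raise EngineError("consultation is finalized")
    if state.proposed is None or diagnosis_id not in {
        d.id for d, _ in state.proposed
    }:
        raise EngineError(f"diagnosis {diagnosis_id!r} was not proposed")
    if decision not in ("accepted", "refused"):
        raise EngineError("decision must be 'accepted' or 'refused'")
    state.reviewed[diagnosis_id] = Review(decision, reason)
    if decision == "refused":
        dx = state.algorithm.diagnoses[diagnosis_id]
        referral = any(
            state.algorithm.managements[m].kind == "referral"
            for m in dx.managements
            if m in state.algorithm.managements
        )
        if referral:
            msg = (
                f"referral-carrying diagnosis '{dx.label}' was refused "
                f"({reason or 'no reason given'}) — referral remains recommended"
            )
            if msg not in state.warnings:
                state.warnings.append(msg)
    return state


def _decision(state: ConsultationState, dx_id: str) -> str:
    r = state.reviewed.get(dx_id)
    return r.decision if r else "accepted"  # inaction must not drop care


def propose_treatments(
    state: ConsultationState, stockout: Iterable[str] = ()
) -> list[TreatmentProposal]:
    """Dose every accepted diagnosis's drugs for this patient.

    First-line drugs in stock-out fall back to the first listed available
    alternative (flagged).  A drug indicated by several diagnoses is
    dispensed once, for the most severe indication.
    """
    if state.proposed is None:
        raise EngineError("diagnoses not yet proposed")
    stockout = set(stockout)
    alg = state.algorithm
    out: list[TreatmentProposal] = []
    drugs_dispensed: set[str] = set()
    for dx, _trace in state.proposed:
        if _decision(state, dx.id) == "refused":
            continue
        for spec in dx.treatments:
            chain = [spec.drug_id] + list(spec.alternative_drug_ids)
            chosen = next((d for d in chain if d not in stockout), None)
            if chosen is None:
                out.append(
                    TreatmentProposal(
                        drug_id=spec.drug_id, indication=dx.id, dose=None,
                        note="all options in stock-out",
                    )
                )
                continue
            if chosen in drugs_dispensed:
                continue  # already dispensed for a more severe indication
            rule = select_rule(
                chosen, dx.id, state.age_days, state.weight_kg,
                alg.dosing_rules.values(),
            )
            dose = compute_dose(rule, alg.drugs[chosen].formulations[0], state.weight_kg)
            out.append(
                TreatmentProposal(
                    drug_id=chosen,
                    indication=dx.id,
                    dose=dose,
                    substituted_for=spec.drug_id if chosen != spec.drug_id else None,
                )
            )
            drugs_dispensed.add(chosen)
    state.proposed_treatments = out
    return out


def referral_recommended(state: ConsultationState) -> bool:
    """Whether any proposed diagnosis carries a referral management
    (computed pre-review: measures the algorithm, not the clinician)."""
    if state.proposed is None:
        raise EngineError("diagnoses not yet proposed")
    alg = state.algorithm
    return any(
        alg.managements[m].kind == "referral"
        for dx, _ in state.proposed
        for m in dx.managements
        if m in alg.managements
    )


def finalize(state: ConsultationState) -> dict:
    """Immutable consultation record for export/audit."""
    if state.proposed is None:
        raise EngineError("cannot finalize before the diagnosis phase")
    if state.proposed_treatments is None:
        propose_treatments(state)
    record = {
        "algorithm_version": state.algorithm.meta.version_id,
        "demographics": {
            "age_days": state.age_days,
            "sex": state.sex,
            "weight_kg": state.weight_kg,
        },
        "answers": [
            {
                "node": nid,
                "value": rec.value,
                "answer": rec.answer_id,
                "estimated": rec.estimated,
                "order": rec.order_index,
            }
            for nid, rec in sorted(
                state.answered.items(), key=lambda kv: kv[1].order_index
            )
        ],
        "emergency_log": list(state.emergency_log),
        "proposals": [
            {
                "diagnosis": dx.id,
                "tier": dx.severity_tier,
                "explanation": trace.rendered,
                "managements": list(dx.managements),
            }
            for dx, trace in state.proposed
        ],
        "reviews": {
            k: {"decision": r.decision, "reason": r.reason}
            for k, r in state.reviewed.items()
        },
        "treatments": [
            {
                "drug": t.drug_id,
                "indication": t.indication,
                "dose": None if t.dose is None else {
                    "quantity": t.dose.quantity,
                    "unit": t.dose.unit,
                    "rendering": t.dose.rendering,
                    "mg_per_kg": t.dose.mg_per_kg,
                    "frequency_per_day": t.dose.frequency_per_day,
                    "duration_days": t.dose.duration_days,
                },
                "substituted_for": t.substituted_for,
                "note": t.note,
            }
            for t in state.proposed_treatments
        ],
        "warnings": list(state.warnings),
        "referral_recommended": referral_recommended(state),
    }
    state.finalized = True
    return record


@dataclass
class CaseOutcome:
    case_id: str
    items_asked: tuple[str, ...]
    diagnoses: tuple[str, ...]
    treatments: tuple[str, ...]
    referral: bool
    warnings: tuple[str, ...]
    error: Optional[str] = None


def run_case(
    alg: ClinicalAlgorithm,
    case: PatientCase,
    stockout: Iterable[str] = (),
    answer_order_rng=None,
) -> CaseOutcome:
    """Replay one batch case end to end.

    ``answer_order_rng`` (a numpy Generator) answers currently-askable
    items in random order instead of presentation order — used to verify
    that answer order never changes clinical outputs.
    """
    try:
        state = start_for_case(alg, case)
        while True:
            items = next_items(state)
            if not items:
                break
            if answer_order_rng is not None:
                node = items[int(answer_order_rng.integers(len(items)))]
            else:
                node = items[0]
            if node.id not in case.answers:
                raise EngineError(f"case {case.id} lacks an answer for {node.id!r}")
            record_answer(
                state, node.id, case.answers[node.id],
                estimated=node.id in case.estimated and node.estimable,
            )
        proposals = propose_diagnoses(state)
        treatments = propose_treatments(state, stockout=stockout)
        return CaseOutcome(
            case_id=case.id,
            items_asked=tuple(
                nid for nid, rec in sorted(
                    state.answered.items(), key=lambda kv: kv[1].order_index
                )
                if alg.nodes[nid].auto_from is None
            ),
            diagnoses=tuple(dx.id for dx, _ in proposals),
            treatments=tuple(sorted(t.drug_id for t in treatments if t.dose is not None)),
            referral=referral_recommended(state),
            warnings=tuple(state.warnings),
        )
    except Exception as e:  # per-case failures are data, not crashes
        return CaseOutcome(
            case_id=case.id, items_asked=(), diagnoses=(), treatments=(),
            referral=False, warnings=(), error=f"{type(e).__name__}: {e}",
        )
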