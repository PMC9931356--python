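"""Validation machinery: lint, corpus replay, non-regression, unit checks.

``lint`` aggregates every static check on the clinical content — the
structural invariants, unreachable diagnoses (decided exactly by
exhaustive enumeration of the relevant question assignments when small
enough, else flagged heuristic), and the dosing-table sweep.
``run_corpus`` replays a batch of cases deterministically;
``non_regression`` diffs two content versions over a shared corpus;
``unit_check`` compares replay output against authored expectations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .conditions import Tri, tri_of
from .dosing import verify_posology
from .engine import CaseOutcome, PatientCase, run_case
from .graph import find_cycle, topological_index
from .model import ClinicalAlgorithm, Diagnosis, Finding, validate_algorithm

ENUMERATION_LIMIT = 2**20


# -- reachability -----------------------------------------------------------


def _closure_nodes(alg: ClinicalAlgorithm, dx: Diagnosis) -> Optional[list[str]]:
    """Condition nodes plus all display-condition ancestors, topologically
    ordered; None if any referenced node is undeclared (dangling)."""
    want = set(dx.condition.node_ids())
    frontier = list(want)
    while frontier:
        nid = frontier.pop()
        node = alg.nodes.get(nid)
        if node is None:
            return None
        if node.display_condition is not None:
            for dep in node.display_condition.node_ids():
                if dep not in want:
                    want.add(dep)
                    frontier.append(dep)
    topo = topological_index(alg)
    return sorted(want, key=lambda n: topo[n])


def _assignment_count(alg: ClinicalAlgorithm, closure: Sequence[str]) -> int:
    total = 1
    for nid in closure:
        node = alg.nodes[nid]
        branches = len(node.answers) + (1 if node.display_condition is not None else 0)
        total *= max(branches, 1)
    return total


def diagnosis_reachable(
    alg: ClinicalAlgorithm, dx: Diagnosis, limit: int = ENUMERATION_LIMIT
) -> Optional[bool]:
    """Exact satisfiability of a diagnosis condition under display gating.

    Enumerates every consistent assignment of the condition's question
    closure (a gated-off question is unanswered and its atoms false).
    Returns True/False, or None when the closure is undecidable here
    (dangling references, or more than ``limit`` assignments).
    """
    closure = _closure_nodes(alg, dx)
    if closure is None:
        return None
    if _assignment_count(alg, closure) > limit:
        return None
    assigned: dict[str, Optional[str]] = {}

    def lookup(node_id: str, answer_id: str) -> Tri:
        if node_id not in assigned:
            return Tri.UNKNOWN
        v = assigned[node_id]
        return tri_of(v == answer_id if v is not None else False)

    def rec(i: int) -> bool:
        if i == len(closure):
            return dx.condition.evaluate(lookup) is Tri.TRUE
        node = alg.nodes[closure[i]]
        if node.display_condition is not None:
            gate = node.display_condition.evaluate(lookup)
            if gate is not Tri.TRUE:
                assigned[node.id] = None  # never asked: atoms false
                ok = rec(i + 1)
                del assigned[node.id]
                return ok
        for a in node.answers:
            assigned[node.id] = a.id
            if rec(i + 1):
                del assigned[node.id]
                return True
        del assigned[node.id]
        return False

    return rec(0)


# -- lint -------------------------------------------------------------------


def lint(
    alg: ClinicalAlgorithm,
    weight_grid: Optional[Sequence[float]] = None,
    age_grid: Optional[Sequence[float]] = None,
) -> list[Finding]:
    """Every static finding on the content, deterministically ordered.

    Aggregates structural validation (cycles, dangling references,
    interval gaps/overlaps, severe diagnoses without referral, ...),
    unreachable-diagnosis detection, and the posology sweep.
    """
    findings = list(validate_algorithm(alg))
    has_cycle = any(f.code == "cycle" for f in findings)
    dangling_subjects = {f.subject for f in findings if f.code == "dangling_reference"}
    if not has_cycle:
        for dx in alg.diagnoses.values():
            if dx.id in dangling_subjects:
                continue  # cannot evaluate a condition with unknown atoms
            reachable = diagnosis_reachable(alg, dx)
            if reachable is False:
                findings.append(
                    Finding(
                        "error",
                        "unreachable_diagnosis",
                        dx.id,
                        "no consistent set of answers satisfies this "
                        "diagnosis condition under display gating",
                    )
                )
            elif reachable is None:
                findings.append(
                    Finding(
                        "warning",
                        "unreachability_heuristic",
                        dx.id,
                        "question closure too large for exhaustive "
                        "enumeration; reachability not decided exactly",
                    )
                )
    findings.extend(verify_posology(alg, weight_grid, age_grid))
    return sorted(set(findings), key=lambda f: (f.code, f.subject, f.message))


# -- exhaustive severity-first sweep ---------------------------------------


def severity_first_sweep(
    alg: ClinicalAlgorithm,
    trigger_nodes: Sequence[str],
    top_tiers: tuple[str, ...] = ("emergency", "severe"),
) -> tuple[int, int]:
    """Exhaustively check the severity-first architecture.

    Enumerates every consistent complete assignment of the algorithm's
    questions (consistent: a question whose display gate is false stays
    unanswered and its atoms are false).  For every assignment where any
    trigger question (e.g. an IMCI danger sign) is answered "yes", the
    top proposed diagnosis must belong to ``top_tiers`` and carry a
    referral management.  Returns (assignments checked, violations).

    Requires exclusion lists that only ever point from more severe to
    less severe diagnoses (then the top proposal is simply the first
    satisfied diagnosis in severity order, as the engine would rank it).
    """
    from .model import severity_rank

    for dx in alg.diagnoses.values():
        for ex in dx.excludes:
            if severity_rank(alg.diagnoses[ex].severity_tier) < severity_rank(
                dx.severity_tier
            ):
                raise ValueError(
                    "sweep requires excludes pointing toward lower severity"
                )
    ordered_dx = sorted(
        alg.diagnoses.values(),
        key=lambda d: (severity_rank(d.severity_tier), alg.diagnosis_order(d.id)),
    )
    referral_ids = {m.id for m in alg.managements.values() if m.kind == "referral"}
    topo = topological_index(alg)
    order = sorted(alg.nodes, key=lambda n: topo[n])
    assigned: dict[str, Optional[str]] = {}

    def lookup(node_id: str, answer_id: str) -> Tri:
        v = assigned.get(node_id)
        return tri_of(v == answer_id if node_id in assigned else None)

    checked = violations = 0

    def visit_leaf() -> None:
        nonlocal checked, violations
        checked += 1
        if not any(assigned.get(t) == "yes" for t in trigger_nodes):
            return
        top = next(
            (dx for dx in ordered_dx if dx.condition.evaluate(lookup) is Tri.TRUE),
            None,
        )
        if (
            top is None
            or top.severity_tier not in top_tiers
            or not any(m in referral_ids for m in top.managements)
        ):
            violations += 1

    def rec(i: int) -> None:
        if i == len(order):
            visit_leaf()
            return
        node = alg.nodes[order[i]]
        if node.display_condition is not None:
            if node.display_condition.evaluate(lookup) is not Tri.TRUE:
                assigned[node.id] = None
                rec(i + 1)
                del assigned[node.id]
                return
        for a in node.answers:
            assigned[node.id] = a.id
            rec(i + 1)
        del assigned[node.id]

    rec(0)
    return checked, violations


# -- corpus replay ----------------------------------------------------------


def run_corpus(
    alg: ClinicalAlgorithm,
    cases: Iterable[PatientCase],
    stockout: Iterable[str] = (),
) -> pd.DataFrame:
    """Deterministic outcome table, one row per case.

    Individual case failures are recorded in the ``error`` column; the
    run continues.
    """
    rows = []
    stockout = tuple(stockout)
    for case in cases:
        o: CaseOutcome = run_case(alg, case, stockout=stockout)
        rows.append(
            {
                "case_id": o.case_id,
                "label": case.label,
                "items_asked": "|".join(o.items_asked),
                "diagnoses": "|".join(o.diagnoses),
                "treatments": "|".join(o.treatments),
                "referral": o.referral,
                "n_warnings": len(o.warnings),
                "error": o.error or "",
            }
        )
    return pd.DataFrame(rows)


# -- non-regression ---------------------------------------------------------


@dataclass(frozen=True)
class CaseDelta:
    case_id: str
    items_added: tuple[str, ...] = ()
    items_removed: tuple[str, ...] = ()
    diagnoses_added: tuple[str, ...] = ()
    diagnoses_removed: tuple[str, ...] = ()
    treatments_added: tuple[str, ...] = ()
    treatments_removed: tuple[str, ...] = ()
    referral_changed: bool = False
    error_changed: bool = False

    @property
    def any_change(self) -> bool:
        return bool(
            self.items_added or self.items_removed
            or self.diagnoses_added or self.diagnoses_removed
            or self.treatments_added or self.treatments_removed
            or self.referral_changed or self.error_changed
        )


@dataclass
class RegressionDiff:
    n_cases: int
    deltas: list[CaseDelta] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not self.deltas

    @property
    def changed_case_ids(self) -> set[str]:
        return {d.case_id for d in self.deltas}

    def summary(self) -> dict[str, int]:
        return {
            "n_cases": self.n_cases,
            "cases_changed": len(self.deltas),
            "items_changed": sum(
                1 for d in self.deltas if d.items_added or d.items_removed
            ),
            "diagnoses_changed": sum(
                1 for d in self.deltas if d.diagnoses_added or d.diagnoses_removed
            ),
            "treatments_changed": sum(
                1 for d in self.deltas if d.treatments_added or d.treatments_removed
            ),
            "referral_changed": sum(1 for d in self.deltas if d.referral_changed),
        }


def non_regression(
    alg_old: ClinicalAlgorithm,
    alg_new: ClinicalAlgorithm,
    cases: Sequence[PatientCase],
    stockout: Iterable[str] = (),
) -> RegressionDiff:
    """Replay the corpus through both versions and diff clinical outputs.

    Identical content yields an empty diff; a localized content change
    produces deltas only in cases whose inputs traverse the changed
    logic.  Question flow (items asked) and terminal outputs (diagnoses,
    treatments, referral) are diffed separably.
    """
    stockout = tuple(stockout)
    diff = RegressionDiff(n_cases=len(cases))
    for case in cases:
        a = run_case(alg_old, case, stockout=stockout)
        b = run_case(alg_new, case, stockout=stockout)
        delta = CaseDelta(
            case_id=case.id,
            items_added=tuple(sorted(set(b.items_asked) - set(a.items_asked))),
            items_removed=tuple(sorted(set(a.items_asked) - set(b.items_asked))),
            diagnoses_added=tuple(sorted(set(b.diagnoses) - set(a.diagnoses))),
            diagnoses_removed=tuple(sorted(set(a.diagnoses) - set(b.diagnoses))),
            treatments_added=tuple(sorted(set(b.treatments) - set(a.treatments))),
            treatments_removed=tuple(sorted(set(a.treatments) - set(b.treatments))),
            referral_changed=a.referral != b.referral,
            error_changed=(a.error or "") != (b.error or ""),
        )
        if delta.any_change:
            diff.deltas.append(delta)
    return diff


# -- unit checks ------------------------------------------------------------


@dataclass(frozen=True)
class Expectation:
    """Authored expected output for one fictional case (pre-review)."""

    case_id: str
    expected_diagnoses: frozenset[str]
    expected_referral: bool
    expected_drugs: Optional[frozenset[str]] = None


@dataclass(frozen=True)
class CheckResult:
    case_id: str
    passed: bool
    detail: str = ""


def unit_check(
    alg: ClinicalAlgorithm,
    cases: Sequence[PatientCase],
    expectations: Sequence[Expectation],
) -> list[CheckResult]:
    """Compare each expectation against the replayed case output."""
    by_id = {c.id: c for c in cases}
    results: list[CheckResult] = []
    for exp in expectations:
        case = by_id.get(exp.case_id)
        if case is None:
            results.append(
                CheckResult(exp.case_id, False, "case not found in corpus")
            )
            continue
        o = run_case(alg, case)
        if o.error:
            results.append(CheckResult(exp.case_id, False, f"engine error: {o.error}"))
            continue
        problems = []
        if set(o.diagnoses) != set(exp.expected_diagnoses):
            problems.append(
                f"diagnoses: expected {sorted(exp.expected_diagnoses)}, "
                f"got {sorted(o.diagnoses)}"
            )
        if o.referral != exp.expected_referral:
            problems.append(
                f"referral: expected {exp.expected_referral}, got {o.referral}"
            )
        if exp.expected_drugs is not None and set(o.treatments) != set(
            exp.expected_drugs
        ):
            problems.append(
                f"drugs: expected {sorted(exp.expected_drugs)}, "
                f"got {sorted(o.treatments)}"
            )
        results.append(
            CheckResult(exp.case_id, not problems, "; ".join(problems))
        )
    return results
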