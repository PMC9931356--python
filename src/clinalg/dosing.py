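"""Weight- and age-band posology.

Dosing rules state a target dose in mg/kg/dose with a tolerated interval
and an absolute per-dose cap, applicable over a half-open age × weight
band.  :func:`compute_dose` turns a rule into a *practical* dose — a
multiple of the formulation's smallest dispensable increment (half
tablets, 0.5 ml of syrup) whose achieved mg/kg is closest to the target
among in-bounds candidates, ties broken toward the lower quantity.
:func:`verify_posology` sweeps an entire algorithm's drug tables across a
weight/age grid and reports every cell that errors or lands out of
bounds, plus band coverage gaps and overlaps — the automated equivalent
of manually checking a posology table for all drugs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .model import ClinicalAlgorithm, DosingRule, Finding, Formulation

_EPS = 1e-9


class DosingError(ValueError):
    pass


class CoverageGapError(DosingError):
    """No dosing band covers the patient's age/weight."""


class BandOverlapError(DosingError):
    """More than one band claims the patient (content defect)."""


class FormulationUnusableError(DosingError):
    """No dispensable quantity achieves a dose inside the tolerated interval."""


@dataclass(frozen=True)
class DoseResult:
    rule_id: str
    form: str
    n_increments: int
    quantity: float  # tablets or ml
    unit: str  # "tablet" | "ml"
    mg_per_dose: float
    mg_per_kg: float
    within_bounds: bool
    frequency_per_day: int
    duration_days: int

    @property
    def rendering(self) -> str:
        if self.unit == "ml":
            return f"{self.quantity:.1f} ml"
        q = self.quantity
        return f"{q:g} tablet" + ("" if q == 1 else "s")


def select_rule(
    drug_id: str,
    indication: str,
    age_days: float,
    weight_kg: float,
    rules: Iterable[DosingRule],
) -> DosingRule:
    """The unique rule whose half-open band contains (age, weight)."""
    matches = [
        r
        for r in rules
        if r.drug_id == drug_id
        and r.indication == indication
        and r.covers(age_days, weight_kg)
    ]
    if not matches:
        raise CoverageGapError(
            f"no dosing band for ({drug_id}, {indication}) covers "
            f"age {age_days:g} d, weight {weight_kg:g} kg"
        )
    if len(matches) > 1:
        ids = ", ".join(r.id for r in matches)
        raise BandOverlapError(
            f"overlapping dosing bands for ({drug_id}, {indication}): {ids}"
        )
    return matches[0]


def compute_dose(
    rule: DosingRule, formulation: Formulation, weight_kg: float
) -> DoseResult:
    """Best dispensable dose for this weight under the rule.

    Candidates are positive multiples of the formulation increment not
    exceeding the absolute per-dose cap.  Among candidates whose achieved
    mg/kg lies inside [min, max], the one closest to the target mg/kg
    wins; an exact tie goes to the lower quantity.  If no candidate is in
    bounds the formulation is unusable at this weight.
    """
    if weight_kg <= 0:
        raise DosingError("weight must be positive")
    step_mg = formulation.step_mg
    max_k = math.floor(rule.max_mg_per_dose / step_mg + _EPS)
    lo_mg = rule.min_mg_per_kg * weight_kg
    hi_mg = rule.max_mg_per_kg * weight_kg
    k_lo = max(1, math.ceil(lo_mg / step_mg - _EPS))
    k_hi = min(max_k, math.floor(hi_mg / step_mg + _EPS))
    if k_hi < k_lo:
        raise FormulationUnusableError(
            f"rule {rule.id}: no multiple of {step_mg:g} mg achieves "
            f"{rule.min_mg_per_kg:g}-{rule.max_mg_per_kg:g} mg/kg at "
            f"{weight_kg:g} kg (cap {rule.max_mg_per_dose:g} mg)"
        )
    target_mg = rule.target_mg_per_kg * weight_kg
    # closest in-bounds multiple; round-half-down implements the low tie-break
    k = int(math.floor(target_mg / step_mg + 0.5 - _EPS))
    k = min(max(k, k_lo), k_hi)
    mg = k * step_mg
    mg_per_kg = mg / weight_kg
    return DoseResult(
        rule_id=rule.id,
        form=formulation.form,
        n_increments=k,
        quantity=k * formulation.increment,
        unit="ml" if formulation.is_liquid else "tablet",
        mg_per_dose=mg,
        mg_per_kg=mg_per_kg,
        within_bounds=(
            rule.min_mg_per_kg - _EPS <= mg_per_kg <= rule.max_mg_per_kg + _EPS
            and mg <= rule.max_mg_per_dose + _EPS
        ),
        frequency_per_day=rule.frequency_per_day,
        duration_days=rule.duration_days,
    )


def default_weight_grid(lo: float = 2.0, hi: float = 25.0, step: float = 0.1) -> np.ndarray:
    """Weights [lo, hi) on a regular grid (half-open, like dosing bands)."""
    n = int(round((hi - lo) / step))
    return np.round(lo + step * np.arange(n), 6)


def default_age_grid(alg: ClinicalAlgorithm, step_days: float = 30.0) -> np.ndarray:
    return np.arange(alg.meta.age_min_days, alg.meta.age_max_days, step_days, dtype=float)


def verify_posology(
    alg: ClinicalAlgorithm,
    weight_grid: Sequence[float] | None = None,
    age_grid: Sequence[float] | None = None,
) -> list[Finding]:
    """Sweep every (drug, indication, formulation) over the grid.

    For every grid cell covered by a band, the practical dose is computed;
    the report lists every cell that errors or lands out of bounds, every
    weight interval of the grid that no band of a (drug, indication)
    covers (coverage gap — the grid is the population the tables must
    serve), and any cell claimed by more than one band.  An empty report
    means the tables are verified over the grid.
    """
    weights = np.asarray(
        default_weight_grid() if weight_grid is None else weight_grid, dtype=float
    )
    ages = np.asarray(
        default_age_grid(alg) if age_grid is None else age_grid, dtype=float
    )
    findings: list[Finding] = []
    pairs: dict[tuple[str, str], list[DosingRule]] = {}
    for r in alg.dosing_rules.values():
        pairs.setdefault((r.drug_id, r.indication), []).append(r)

    for (drug_id, indication), rules in sorted(pairs.items()):
        drug = alg.drugs.get(drug_id)
        if drug is None:
            continue  # dangling reference; static validation reports it
        # ages with the same applicable rule set sweep identically: keep one
        representative: dict[tuple[str, ...], float] = {}
        for age in ages:
            key = tuple(r.id for r in rules if r.age_lo_days <= age < r.age_hi_days)
            representative.setdefault(key, float(age))
        for key, age in representative.items():
            age_rules = [r for r in rules if r.id in key]
            if not age_rules:
                continue
            gap_lo: float | None = None
            for w in weights:
                matches = [r for r in age_rules if r.covers(age, w)]
                if len(matches) > 1:
                    findings.append(
                        Finding(
                            "error",
                            "band_overlap",
                            matches[0].id,
                            f"({drug_id}, {indication}): bands "
                            f"{', '.join(r.id for r in matches)} all cover "
                            f"age {age:g} d, {w:g} kg",
                        )
                    )
                if not matches:
                    if gap_lo is None:
                        gap_lo = float(w)
                    continue
                if gap_lo is not None:
                    findings.append(
                        Finding(
                            "error",
                            "band_gap",
                            f"{drug_id}:{indication}",
                            f"no band covers weights [{gap_lo:g}, {w:g}) "
                            f"at age {age:g} d",
                        )
                    )
                    gap_lo = None
                if not matches:
                    continue
                rule = matches[0]
                for form in drug.formulations:
                    try:
                        res = compute_dose(rule, form, float(w))
                    except FormulationUnusableError as e:
                        findings.append(
                            Finding("error", "dose_out_of_bounds", rule.id, str(e))
                        )
                        continue
                    if not res.within_bounds:
                        findings.append(
                            Finding(
                                "error",
                                "dose_out_of_bounds",
                                rule.id,
                                f"{form.form} at {w:g} kg achieves "
                                f"{res.mg_per_kg:.2f} mg/kg outside "
                                f"[{rule.min_mg_per_kg:g}, {rule.max_mg_per_kg:g}]",
                            )
                        )
            if gap_lo is not None:
                end = float(weights[-1]) + (
                    float(weights[-1] - weights[-2]) if len(weights) > 1 else 0.0
                )
                findings.append(
                    Finding(
                        "error",
                        "band_gap",
                        f"{drug_id}:{indication}",
                        f"no band covers weights [{gap_lo:g}, {round(end, 6):g}) "
                        f"at age {age:g} d",
                    )
                )
    # deterministic, de-duplicated report (the same defect often recurs
    # across the age grid)
    uniq = sorted(set(findings), key=lambda f: (f.code, f.subject, f.message))
    return uniq
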