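"""Likelihood-ratio algebra for designing algorithm branches.

A branch that proposes a treatment behaves like a diagnostic test: its
sensitivity and specificity give likelihood ratios
``LR+ = sens / (1 - spec)`` and ``LR- = (1 - sens) / spec``, which
multiply pre-test odds (disease prevalence in the presenting population)
into post-test odds.  The design questions this module answers:

* what probability of disease does a positive branch imply here?
  (:func:`post_test_probability`)
* how strong must a branch be so that a positive reaches a target
  post-test probability at this prevalence? (:func:`required_lr`) — a
  rarer condition demands a higher LR;
* given a continuous marker's ROC grid (e.g. a CRP-style test), which
  cutoff reaches the target?  (:func:`choose_cutoff`) — at a higher
  pre-test probability (comorbidities) a *lower* cutoff suffices,
  buying sensitivity at the same post-test probability;
* what sensitivity/specificity does a branch actually achieve on a
  labelled case corpus? (:func:`branch_performance`)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from statsmodels.stats.proportion import proportion_confint


def _check_prob(p: float, name: str) -> None:
    if not 0.0 < p < 1.0:
        raise ValueError(f"{name} must lie strictly inside (0, 1), got {p}")


def lr_pos(sensitivity: float, specificity: float) -> float:
    _check_prob(sensitivity, "sensitivity")
    _check_prob(specificity, "specificity")
    return sensitivity / (1.0 - specificity)


def lr_neg(sensitivity: float, specificity: float) -> float:
    _check_prob(sensitivity, "sensitivity")
    _check_prob(specificity, "specificity")
    return (1.0 - sensitivity) / specificity


def post_test_probability(pretest: float, lr: float) -> float:
    """Posterior disease probability after a test with likelihood ratio lr.

    Odds form of Bayes' theorem: post-odds = pre-odds × LR.
    """
    _check_prob(pretest, "pretest")
    if lr <= 0:
        raise ValueError(f"likelihood ratio must be positive, got {lr}")
    odds = pretest / (1.0 - pretest) * lr
    return odds / (1.0 + odds)


def required_lr(pretest: float, target_posttest: float) -> float:
    """The likelihood ratio needed to move pretest to target_posttest.

    Strictly decreasing in pretest: a rarer condition needs a stronger
    test to reach the same post-test probability.
    """
    _check_prob(pretest, "pretest")
    _check_prob(target_posttest, "target_posttest")
    pre_odds = pretest / (1.0 - pretest)
    post_odds = target_posttest / (1.0 - target_posttest)
    return post_odds / pre_odds


@dataclass(frozen=True)
class PrevalenceContext:
    """Pre-test probability, optionally adjusted upward for comorbidity."""

    pretest: float
    comorbid_pretest: Optional[float] = None

    def __post_init__(self) -> None:
        _check_prob(self.pretest, "pretest")
        if self.comorbid_pretest is not None:
            _check_prob(self.comorbid_pretest, "comorbid_pretest")


@dataclass(frozen=True)
class Wilson:
    estimate: float
    lo: float
    hi: float


def _wilson(k: int, n: int, alpha: float = 0.05) -> Optional[Wilson]:
    if n == 0:
        return None
    lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
    return Wilson(k / n, float(lo), float(hi))


@dataclass(frozen=True)
class BranchPerformance:
    """Empirical branch test characteristics with 95% Wilson intervals.

    Undefined quantities (zero denominators — e.g. specificity on an
    all-positive label set, or LR+ when specificity is exactly 1) are
    reported as None, never fabricated.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def sensitivity(self) -> Optional[Wilson]:
        return _wilson(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> Optional[Wilson]:
        return _wilson(self.tn, self.tn + self.fp)

    @property
    def lr_pos(self) -> Optional[float]:
        se, sp = self.sensitivity, self.specificity
        if se is None or sp is None or sp.estimate == 1.0:
            return None
        return se.estimate / (1.0 - sp.estimate)

    @property
    def lr_neg(self) -> Optional[float]:
        se, sp = self.sensitivity, self.specificity
        if se is None or sp is None or sp.estimate == 0.0:
            return None
        return (1.0 - se.estimate) / sp.estimate


@dataclass(frozen=True)
class RocPoint:
    cutoff: float
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class RocGrid:
    """Cutoff → (sensitivity, specificity) grid for a continuous marker.

    Along increasing cutoff, sensitivity must be non-increasing and
    specificity non-decreasing (the usual ROC trade-off).
    """

    points: tuple[RocPoint, ...]

    def __post_init__(self) -> None:
        pts = self.points
        if not pts:
            raise ValueError("empty ROC grid")
        for p in pts:
            _check_prob(p.sensitivity, "sensitivity")
            _check_prob(p.specificity, "specificity")
        for a, b in zip(pts, pts[1:]):
            if not a.cutoff < b.cutoff:
                raise ValueError("cutoffs must be strictly increasing")
            if b.sensitivity > a.sensitivity + 1e-12:
                raise ValueError("sensitivity must be non-increasing in cutoff")
            if b.specificity < a.specificity - 1e-12:
                raise ValueError("specificity must be non-decreasing in cutoff")

    @staticmethod
    def from_rows(rows: Sequence[tuple[float, float, float]]) -> "RocGrid":
        return RocGrid(tuple(RocPoint(*r) for r in rows))


@dataclass(frozen=True)
class CutoffChoice:
    cutoff: float
    posttest: float
    reached_target: bool


def choose_cutoff(grid: RocGrid, pretest: float, target_posttest: float) -> CutoffChoice:
    """Lowest cutoff whose positive result reaches the target post-test
    probability; if none does, the best achievable is returned flagged.

    Because higher pretest probability lowers the LR needed, the chosen
    cutoff is non-increasing in pretest — with comorbidities a lower
    marker cutoff reaches the same post-test probability with more
    sensitivity.
    """
    _check_prob(pretest, "pretest")
    _check_prob(target_posttest, "target_posttest")
    best: Optional[CutoffChoice] = None
    for p in grid.points:  # ascending cutoff
        post = post_test_probability(pretest, lr_pos(p.sensitivity, p.specificity))
        if post >= target_posttest:
            return CutoffChoice(p.cutoff, post, True)
        if best is None or post > best.posttest:
            best = CutoffChoice(p.cutoff, post, False)
    assert best is not None
    return best


def branch_performance(alg, diagnosis_id: str, cases) -> BranchPerformance:
    """Empirical sensitivity/specificity of one diagnosis branch.

    Each labelled case is replayed through the engine; the branch is
    "positive" when the diagnosis is proposed pre-review (the clinician's
    accept/refuse is excluded — this measures the algorithm, not the
    user).  Gold truth: the case's label equals the diagnosis id.
    """
    from .engine import run_case

    if diagnosis_id not in alg.diagnoses:
        raise ValueError(f"unknown diagnosis {diagnosis_id!r}")
    tp = fp = fn = tn = 0
    for case in cases:
        if case.label is None:
            raise ValueError(f"case {case.id} carries no gold label")
        outcome = run_case(alg, case)
        if outcome.error:
            raise RuntimeError(f"case {case.id} failed: {outcome.error}")
        positive = diagnosis_id in outcome.diagnoses
        diseased = case.label == diagnosis_id
        if diseased and positive:
            tp += 1
        elif diseased:
            fn += 1
        elif positive:
            fp += 1
        else:
            tn += 1
    return BranchPerformance(tp=tp, fp=fp, fn=fn, tn=tn)
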