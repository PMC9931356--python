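"""Designing an algorithm branch with likelihood ratios.

How strong must a branch be to justify an antibiotic at a given disease
prevalence, which CRP cutoff achieves it, and what does the branch
actually achieve on a labelled synthetic corpus?
"""

from clinalg import (
    RocGrid,
    branch_performance,
    build_fixture_algorithm,
    choose_cutoff,
    post_test_probability,
    required_lr,
)
from clinalg.casegen import default_profiles, generate_cases

# a rarer condition needs a stronger test for the same post-test probability
for prevalence in (0.05, 0.20):
    lr = required_lr(prevalence, 0.5)
    print(f"prevalence {prevalence:.2f}: LR+ >= {lr:5.1f} needed to reach "
          f"post-test 0.50 (check: {post_test_probability(prevalence, lr):.2f})")

# invented demo ROC grid for a CRP-style marker
grid = RocGrid.from_rows([
    (10, 0.95, 0.40), (20, 0.85, 0.60), (40, 0.70, 0.85), (80, 0.50, 0.95),
])
for pretest, who in ((0.05, "no comorbidity"), (0.15, "with comorbidity")):
    c = choose_cutoff(grid, pretest, target_posttest=0.35)
    print(f"{who} (pre-test {pretest:.2f}): cutoff {c.cutoff:g} mg/L "
          f"-> post-test {c.posttest:.2f}")
# the comorbid child gets the LOWER cutoff: more sensitivity, same post-test

alg = build_fixture_algorithm()
cases = generate_cases(default_profiles(), 1000, seed=21)
perf = branch_performance(alg, "pneumonia", cases)
se, sp = perf.sensitivity, perf.specificity
print(f"\npneumonia branch on 1000 labelled cases: "
      f"TP={perf.tp} FP={perf.fp} FN={perf.fn} TN={perf.tn}")
print(f"  sensitivity {se.estimate:.3f} (95% CI {se.lo:.3f}-{se.hi:.3f})")
print(f"  specificity {sp.estimate:.3f} (95% CI {sp.lo:.3f}-{sp.hi:.3f})")
print(f"  LR+ {perf.lr_pos:.1f}, LR- {perf.lr_neg:.2f}")
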