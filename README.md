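# clinalg

Boolean decision-tree clinical algorithms — the kind that guide a nurse or
non-physician clinician through a pediatric outpatient consultation from
symptoms, signs and point-of-care tests to diagnoses, referral decisions and
weight-band drug doses — treated as auditable, testable software.

The package is aimed at teams who author and maintain such clinical decision
support content: it gives them a validated machine-readable (and still
human-readable) document format, a deterministic execution engine, the
branch-design mathematics, and an automated QA harness, exercised end to end
on a packaged synthetic demo algorithm and seeded synthetic patient cases.

## What is inside

- **`clinalg.model` / `clinalg.io`** — the algorithm document: staged
  questions with threshold-coded answers (half-open intervals `[lo, hi)`, so
  "MUAC < 12.5 cm" is a category boundary), Boolean display conditions with
  an `AT_LEAST(k)` counting connective for composite clinical-impression
  items, severity-tiered diagnoses, managements, and per-kg dosing tables.
  One schema, two dialects (YAML authoring, canonical JSON exchange);
  `deserialize(serialize(a)) == a` byte-stably. Validation reports *every*
  violated invariant at once.
- **`clinalg.engine`** — deterministic consultation execution under
  Kleene three-valued logic (true/false/unknown): a question becomes askable
  only when its display condition is definitely true; at diagnosis time a
  gated-off question's atoms are false. Severity-first proposals
  (emergency > severe > moderate > mild) with minimal explanation traces, an
  emergency interrupt usable at any point with no effect on clinical
  outputs, accept/refuse review with an audit trail, and treatment proposals
  with stock-out alternatives.
- **`clinalg.dosing`** — practical doses: the multiple of the smallest
  dispensable increment (half tablet, 0.5 ml) whose achieved mg/kg is
  closest to the target within the tolerated interval `[min, max]` and the
  absolute cap; plus a whole-table sweep across an age × weight grid.
- **`clinalg.bayes`** — branch design by likelihood ratios. With pre-test
  odds `o = p/(1-p)` and `LR+ = sens/(1-spec)`, the post-test probability of
  a positive branch is `o·LR / (1 + o·LR)`; `required_lr` inverts this, and
  `choose_cutoff` picks the lowest marker cutoff (e.g. CRP) reaching a
  target post-test probability — at a higher pre-test probability
  (comorbidity) a lower cutoff suffices. `branch_performance` measures a
  branch's empirical sensitivity/specificity on labelled cases with 95%
  Wilson intervals.
- **`clinalg.casegen`** — the demo algorithm and a seeded generator of
  labelled synthetic cases (six condition profiles, prevalences skewed
  toward non-severe children), plus seeded defect injection (`corrupt`) for
  QA testing.
- **`clinalg.qa`** — lint (structural checks, exact unreachable-diagnosis
  detection by exhaustive enumeration, dosing sweep), deterministic corpus
  replay, non-regression diffs between content versions, and
  expectation-based unit checks.

## Worked example

```sh
python examples/run_consultation.py
```

drives one consultation (2-year-old, 10 kg, febrile, CRP 75 mg/L, with an
emergency interrupt mid-way and amoxicillin in stock-out) and prints:

```
proposed diagnoses (severity-first):
  moderate  Bacterial infection likely (CRP branch)  because CRP point-of-care test = >= 40 mg/L; Fever (reported or measured) = yes
  mild      Fever without bacterial indication  because Fever (reported or measured) = yes

treatments (amoxicillin in stock-out):
  cotrimoxazole (substituted for amoxicillin): 5.0 ml = 24.0 mg/kg, 2x/day for 5 days
  paracetamol: 6.0 ml = 14.4 mg/kg, 4x/day for 3 days

export: version demo-1.0.0, referral recommended: False, 16 answers, 1 emergency interrupt(s)
```

The explanation lines are the minimal answer sets that satisfy each
diagnosis condition; the doses are dispensable quantities (ml of
suspension/syrup) achieving a per-kg dose inside each drug's tolerated
interval; the interrupt left the clinical outputs untouched.

`examples/branch_design.py` shows the design math — at prevalence 0.05 a
branch needs LR+ ≥ 19 to reach a post-test probability of 0.50 whereas at
0.20 it needs only 4, and on a demo ROC grid the comorbid (higher pre-test)
child gets the 40 mg/L cutoff where the non-comorbid child needs 80 mg/L.
The other examples cover validation/lint, dose checking, and non-regression
diffs. A thin `clinalg` CLI wraps the same operations
(`validate`, `run`, `dose-check`, `bayes`, `casegen`, `regress`,
`unit-check`).

## Limitations

The packaged algorithm and case generator are synthetic demo content: the
two printed clinical thresholds (MUAC 12.5 cm, SpO₂ 90%) are the standard
cutoffs, everything else (CRP cutoffs, respiratory-rate thresholds, dosing
figures, prevalences) is invented for exercising the machinery. See
`docs/methods.md` for the model, its assumptions, and what the tests do and
do not establish about real clinical content.
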