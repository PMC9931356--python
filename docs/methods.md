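# Methods

## The algorithm model

A clinical algorithm is a finite set of *nodes* (questions) partitioned
into ordered stages (registration, first look, complaints, vitals, signs,
tests), a set of severity-tiered *diagnoses* with Boolean conditions over
(node, answer) atoms, *managements* (referral, pre-referral treatment,
counselling, follow-up), and drug *dosing tables*. Everything is plain
data with a canonical serialization, so content versions can be diffed,
hashed and replayed.

Units are fixed: ages in days (month lengths are ambiguous at the ages
that matter most here), weights in kg, temperatures in °C. Numeric answers
are half-open intervals `[lo, hi)` that must partition the node's
admissible range; a strict-inequality cutoff like "< 12.5 cm" is therefore
representable exactly as a category boundary, and the boundary value
itself belongs to the upper category.

Conditions are expression trees over atoms with AND, OR, NOT and
`AT_LEAST(k, atoms)`. The counting connective exists because composite
clinical-impression items ("2 of 4 severity signs") and any-danger-sign
logic are idiomatic in this content and clumsy to expand into DNF.

Terminology codes are auto-assigned as a stable digest of
(algorithm name, version, id) — deterministic across rebuilds. No mapping
to an external code standard is attempted.

Validation collects *all* violations rather than failing fast: the
intended author is a clinician working without programming support, and a
complete defect list per run is the difference between a review cycle and
many.

## Execution semantics

Atoms are three-valued (Kleene strong logic). During questioning an
unanswered atom is *unknown*; a node is askable only when its display
condition is definitely true, which prevents a question from being
skipped or shown prematurely while its gate is still undetermined.
Question order is stage order, then topological order of the
display-dependency graph (ties by authoring order) — the dependency graph
must be acyclic, which validation enforces.

At diagnosis time the engine re-reads every atom: answered atoms are
true/false; an unanswered node whose display condition resolves false was
legitimately never asked and its atoms count as false (skipped branches
cannot contribute); an unanswered node whose gate is true or undetermined
is an error the engine reports by node id. This makes the proposal a pure
function of the answer *set* — answer order can never change outputs,
which the tests verify by permutation and which underwrites non-regression
diffing.

Proposals are severity-first: diagnoses whose conditions hold, minus those
suppressed by an active diagnosis's exclusion list, ordered
emergency > severe > moderate > mild with authoring order as tie-break.
Each proposal carries a minimal explanation: a greedily irreducible partial
assignment that alone satisfies the condition (replayed under Kleene
semantics with all other atoms unknown).

Design choices where the design was genuinely open:

- *Estimated values* (allowed only on nodes flagged estimable) enter the
  logic exactly like measured ones; they are flagged and produce a
  "sub-optimal" warning that survives into the export. Estimation exists
  to keep a consultation moving, not to change semantics.
- *Refusing* a referral-carrying diagnosis removes its treatments but not
  the referral warning from the export: the clinician's autonomy is
  respected, the audit trail is preserved.
- Diagnoses left unreviewed at treatment time default to accepted —
  inaction must not silently drop care.
- The emergency interrupt returns guidance immediately at any point,
  appends a log record, and is side-effect-free on clinical outputs.
- Previously recorded answers are never deleted when later answers would
  have gated their question off; askability is recomputed continuously but
  recording is append-only (same-value re-entry is an idempotent no-op).

## Dosing

A dosing rule gives a target dose in mg/kg/dose with a tolerated interval
`[min, max]`, an absolute per-dose cap, frequency and duration, applicable
over a half-open age × weight band; bands for the same (drug, indication)
must be disjoint and a patient must fall in exactly one. The practical
dose is the multiple of the formulation's smallest dispensable increment
whose achieved mg/kg is closest to the target among candidates inside the
tolerated interval and under the cap, with exact ties broken toward the
lower quantity (never silently overdose). This objective is a design
choice; the closed-form implementation is verified against an exhaustive
minimizer on randomized draws.

`verify_posology` sweeps every (drug, indication, formulation) over a
weight grid (default 2.0–25.0 kg in 0.1 kg steps, half-open) × age grid
(default monthly; ages with identical applicable rule sets are swept
once). The grid is treated as the population the tables must serve, so a
deleted band surfaces as a coverage gap even at the edge of the table.
0.1 kg resolution is cheap and bounds the miss risk because increment
switch points are sparse. Doses are per-dose (frequency carried as
metadata), and per-dose is the convention throughout.

## Branch design mathematics

Standard diagnostic-test algebra in odds form: `LR+ = sens/(1−spec)`,
`LR− = (1−sens)/spec`, post-test odds = pre-test odds × LR. `required_lr`
is its exact inverse and is strictly decreasing in pre-test probability: a
branch for a rare condition must be much stronger to justify the same
action. `choose_cutoff` scans an ROC grid (cutoffs strictly increasing,
sensitivity non-increasing, specificity non-decreasing) for the lowest
cutoff whose positive result reaches the target post-test probability,
returning the best achievable (flagged) when none does. Because the
required LR falls as pre-test probability rises, the chosen cutoff is
non-increasing in pre-test probability — the comorbidity rule: a child
with a higher prior probability of needing antibiotics gets a lower
marker cutoff, buying sensitivity at the same post-test probability.

Empirical branch performance counts a diagnosis as positive when it is
*proposed*, before clinician review — the quantity measures the
algorithm, not the user. Confidence intervals are 95% Wilson score
intervals; quantities with zero denominators (specificity on an
all-positive corpus, LR+ at specificity 1) are reported as undefined,
never fabricated.

## Synthetic content and generator

The demo algorithm is structurally faithful to severity-first pediatric
outpatient content: four danger-sign questions feeding an emergency
diagnosis; a 2-of-4 composite clinical-impression item; SpO₂ < 90%,
MUAC < 12.5 cm and fast-breathing-for-age branches; a fever-gated
CRP-style test with a standard (40 mg/L) and a lowered comorbidity
(20 mg/L) cutoff; three drugs with two weight bands each and
alternatives; and a supportive-care catch-all. The two printed
thresholds (12.5 cm, 90%) are the standard clinical cutoffs; every other
number is invented demo content, because real national content is
maintained by health authorities and is not printed anywhere this package
could reproduce it from.

The case generator draws a condition label by prevalence weight
(six profiles, 40% well children, 7% very severe — skewed toward
non-severe as outpatient populations are), then each boolean predictor
from a per-condition Bernoulli probability and each numeric predictor
from a normal or log-normal law truncated by rejection to the node's
admissible range. Reported design means are the truncated means in
closed form, so fidelity tests compare the sample against exactly what
the generator samples. Ages are uniform within a profile band and weight
follows a simple age-median growth curve with 10% noise, clipped to
2.5–24.5 kg so every generated case is dosable.

What the generator does *not* emulate: inter-predictor correlation beyond
the shared condition label, measurement error (beyond the estimated-value
flag), missingness, or any real country's epidemiology. Passing tests
therefore demonstrate that the machinery is correct on content of this
shape — not that any particular clinical content is valid.

## QA machinery

Lint aggregates structural validation, reachability and the posology
sweep with a deterministic ordering. Unreachability is decided *exactly*:
for each diagnosis the engine enumerates every consistent assignment of
the question closure (the condition's nodes plus their display-condition
ancestors; a gated-off node stays unanswered with atoms false). If the
closure exceeds 2^20 assignments the diagnosis is flagged as undecided
with an explicit warning rather than silently guessed. Diagnoses whose
conditions contain dangling references are skipped (the dangling finding
already covers them).

Non-regression replays a fixed corpus through two content versions and
diffs, separably, the questions asked and the terminal outputs
(diagnoses, treatments, referral flag). The tests verify localization
directly: a single CRP-cutoff change diffs exactly the case set computed
from raw inputs (febrile, CRP inside the moved interval, no comorbidity,
no danger sign) and nothing else.

## Problem sizes and numerics

Default scales: the severity-first sweep enumerates all ~98,000
consistent assignments of the demo algorithm exhaustively; engine
determinism uses 1,000 cases × 5 random answer orders; Bayes simulations
use 20 triples × 100,000 Bernoulli draws (3 SE tolerance); dose rounding
is checked against brute force on 1,000 random draws; generator fidelity
uses n = 10,000 with exact-binomial 99% CIs for prevalences and 3 SE for
truncated means (plus 0.02 slack for the 2-decimal rounding of stored
values). Floating-point comparisons in dosing use a 1e-9 guard so that
band boundaries and exact-divisibility cases are stable; the
closest-multiple computation uses round-half-down to implement the
lower-quantity tie-break in closed form.

## Known limitations

- Conditions support no arithmetic over raw values (only threshold
  categories) and no scores/weighted sums beyond `AT_LEAST`.
- One formulation per drug is exercised by the demo content; the sweep
  checks all formulations of a drug against every band, which is
  conservative for drugs whose formulations target disjoint weight
  ranges.
- The interactive CLI mode is a convenience, not a clinical UI; media
  help references are opaque strings.
- No EMR/HMIS integration, offline sync, or multi-device state.
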