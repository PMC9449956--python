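# Methods

## Problem and data model

Unilateral facial paralysis (FP) weakens the voluntary facial muscles on one
side of the face. The severity grading task here is seven-way: normal, plus
{mild, moderate, severe} for each of the left and right sides. The input to
classification is one *session*: a subject performs five voluntary movements
(smiling, eye closure, eyebrow raising, cheek blowing, whistling) plus rest,
and a depth sensor reports 17 facial animation units (FAUs) per state —
continuous muscle-activation values in [0, 1]. A session therefore carries
6 × 17 = 102 raw values.

Twelve FAUs form six left/right pairs — eye closure (FAU2/3), eyebrow raiser
(FAU4/5), lip-corner puller (FAU6/7), lip-corner depressor (FAU8/9),
lower-lip depressor (FAU10/11), cheek puff (FAU16/17) — with the convention
*even index = left side*. FAU14 (lip pucker) is midline and unpaired. The
pair assignment and the side convention are fixed by this package's schema;
upstream capture systems name only the pairs, not the index parity.

## Feature transformation

Two transformations produce the classifier input:

* **Animation symmetry index (ASI).** For each pair and each state,
  `ASI = |left − right|`. This is the simplest index consistent with
  comparing the two facial sides; a normalized variant
  `|L − R| / (L + R + ε)` (ε = 1e−6) is available via a switch, since
  upstream symmetry modules differ in normalization and any SVM
  hyperparameters quoted for one scale need not transfer to the other.
  6 pairs × 6 states = 36 ASIs; the 6 rest-state ASIs are excluded from
  classification (at rest a healthy and a paralysed face are both near
  symmetric), leaving 30.
* **Facial function grade.** For each movement's most-affected FAUs
  (FAU6/7 smiling, FAU2/3 eye closure, FAU4/5 eyebrow raise, FAU16/17 cheek
  blow, FAU14/16/17 whistle), `grade = value during movement − value at
  rest`, signed: the sign carries the direction of activation, and a
  paralysed side shows a smaller grade. 11 values.

Concatenated (movement-major, ASIs before grades) these give the canonical
41-vector. Each movement owns a feature subset — its six ASIs plus its
grades: 8 features for four movements, 9 for whistling — and these subsets
partition the 41 features. The feature-count bookkeeping (102 raw; 72 slots
into the symmetry module; 20 into the grading module; 74 distinct) is
derived from the schema at run time, not hard-coded.

## Class imbalance: a hybrid of three techniques

1. **Random undersampling** of the normal class (1650 captured sessions)
   down to 289, the size of the largest patient class context; removal is
   uniform without replacement.
2. **SMOTE oversampling** of every minority class up to the majority count.
   A synthetic sample is `x_i + u (x_nn − x_i)`, `u ~ U(0,1)`, with `x_i` a
   uniformly drawn seed row of the class and `x_nn` one of its k = 5 nearest
   same-class neighbours (Euclidean distance in the 41-dim feature space;
   neighbour search over the class's original rows only). k falls back to
   class size − 1 with a warning for very small classes. Synthetic rows are
   flagged in a provenance column. SMOTE operates on transformed features,
   matching the pipeline order (transform precedes resampling and
   classification).
3. **Threshold moving** at prediction time: if the normal class wins the
   probability argmax but with probability below 0.4, it is excluded and the
   second-ranked class is returned. The value 0.4 reflects the observed
   separation between normal and patient probability mass in the original
   study's classifiers; it is configurable.

In the train/test path, SMOTE is applied to the training part only
(leakage-safe default); an `augment_before_split` switch reproduces the
alternative order in which augmentation precedes splitting.

## Two-level ensemble

**First level.** Five classifiers, one per voluntary movement, each trained
only on its movement's 8-9 features. RBF-kernel SVMs are primary; features
are standardized with training statistics inside each model pipeline (RBF
kernels over mixed-scale features need comparable scales; random-forest
baselines are fit unscaled). Probabilities come from sigmoid (Platt)
calibration with pairwise coupling, fitted on unshuffled stratified folds so
refits are deterministic. Hyperparameters are chosen by exhaustive grid
search — C over 10⁻³…10⁸ and gamma over 10⁻³…10³ (84 cells) — scored by
stratified five-fold CV mean accuracy, with ties broken toward the smallest
C then the smallest gamma. Baselines: K-NN swept over k = 1…9 and random
forests over max_depth 1…10 × n_estimators {5, 10, 20, 30, 50, 100}.

**Second level.** A deterministic rule-based combiner over the five votes:

1. strict majority (≥ 3 votes) wins;
2. a unique plurality at 2 votes wins;
3. two classes tied at 2 votes: if exactly one is normal, the other wins
   (`tie_rule_a`); otherwise the tied class with the larger probability mass
   summed over the five classifiers wins (`tie_rule_b`);
4. five distinct votes: highest summed probability wins
   (`prob_sum_fallback`).

Rules 3-4 are this package's design (the original flowchart's conditions
are not public); they are biased against the normal class, consistent with
the threshold-moving strategy, and the applied branch is logged per
prediction so behaviour is auditable. Exact probability ties break by label
symbol, keeping the combiner order-invariant and deterministic.

**Splitting.** Train+validation vs test at ratio 0.8 (≈ 4:1), stratified:
the per-class test allocation rounds down, and the remaining slots (to reach
`round(0.2 n)`) go to the classes with the largest fractional remainders, so
every class stays within one sample of its exact proportion.

## Evaluation

Per-class metrics are one-vs-rest percentages (accuracy, precision,
sensitivity, specificity, F1) computed from TP/FP/FN/TN; zero-denominator
metrics are reported as undefined (NaN, flagged), never coerced. Macro
averages skip undefined cells; micro accuracy (trace/n) is always reported
alongside, because per-classifier aggregate accuracies published for this
method are not reconstructible as either plain macro or micro averages of
the published per-class table. Display rounding is one decimal, half away
from zero; internal values keep full precision.

A reference confusion matrix — the original study's held-out ensemble
result over the five available categories (n = 135) — ships as a CSV
fixture and serves as a metric oracle: recomputing from its raw counts
recovers the reported per-class sensitivities and specificities (e.g.
normal 100% sensitivity, 84.2% specificity; right-moderate 87.5%
sensitivity). One published per-class accuracy (92 for the right-severe
class) is inconsistent with that matrix, which implies 100; this package
always reports matrix-derived values.

**Robustness protocol.** Five-fold CV repeated five times with different
shuffles, with and without SMOTE augmentation, reporting mean ± SD of
accuracy, precision, sensitivity and macro F1 per movement classifier. Two
augmentation scopes exist. With `augment_scope="dataset"` (default for this
protocol, matching the original study's near-ceiling published numbers)
SMOTE balances the whole set before folding, so synthetic rows also appear
in validation folds; augmentation then raises mean accuracy and shrinks its
SD. With the leakage-safe `augment_scope="fold"`, validation folds keep the
real imbalance; balanced training then *lowers* micro accuracy on the
majority class even as minority recall improves — so the mean-accuracy-up
pattern is a statement about the dataset-scope protocol, not about
generalization to unseen imbalanced data. The train/test pipeline path is
unaffected: it stays leakage-safe by default.

## Synthetic cohort generator

The patient data are not deposited, so the generator emulates the
*structure* the classifier exploits rather than any individual patient:

* class counts default to the study's frequencies (289 normal after
  undersampling; 127/35/177/36 patient records; left-moderate and
  left-severe are absent, as in the study); the originally captured 1650
  normal sessions are available via a count override;
* a healthy activation template assigns each movement's primary muscle
  pairs activation 0.8 (0.5-0.7 for the whistle group, 0.3 for synergists),
  rest is zero;
* a record with side *s* and severity *v* multiplies the side-*s* member of
  every active pair by an attenuation factor — none 1.0, mild 0.65,
  moderate 0.35, severe 0.10 (strictly decreasing, configurable); the
  midline pucker FAU14 is attenuated by `(1 + a)/2` since both sides
  contribute to it;
* i.i.d. Gaussian noise (SD 0.05 by default, roughly the short-term
  repeat-measurement jitter plausible for sensor-derived activation units)
  is added, then values are clipped to [0, 1].

What it does **not** emulate: between-subject anatomy and expressiveness
differences, session-to-session drift, correlated (non-diagonal) noise,
partial or region-specific paralysis patterns, mislabeled ground truth, and
repeated records from the same patient (real records cluster by patient;
synthetic records are exchangeable). Consequently, passing results on
synthetic cohorts demonstrate that the implementation recovers the planted
side/severity structure under measurement noise — not that the published
real-data accuracies would be reproduced on new patients.

## Numerical and scale choices

* Deterministic seeding throughout: every stochastic step (generation,
  undersampling, SMOTE, splitting, CV shuffles, model fits) takes an
  explicit seed; a pipeline run derives per-stage seeds from one master
  seed and logs them.
* Grid-search CV folds are fixed once per search, so the result is
  invariant to cell evaluation order.
* End-to-end runs in the examples, the tests and the acceptance script use
  a reduced 4×4 subgrid (C ∈ {1, 10, 100, 1000}, gamma ∈ {0.01, 0.1, 1,
  10}) and study-sized cohorts (n ≈ 660); on standardized synthetic
  features the selected cells sit in the interior of this subgrid. The full
  84-cell grids remain the library defaults.
* Records failing validation (missing movements, non-numeric or
  out-of-range FAUs, unknown labels) raise parse errors naming the
  offending record and field; a lenient mode clips out-of-range values with
  a warning.

## Known limitations

* The ASI normalization of the original capture system is unknown; absolute
  hyperparameter values therefore do not transfer between ASI variants.
* The combiner's tie rules beyond the 2-2-with-normal case are design
  choices, exercised in tests but not validated against clinical data.
* With zero noise, whole classes collapse to identical points; SMOTE then
  reproduces duplicates and standardization zeroes constant columns — both
  handled, but such cohorts exercise bookkeeping more than learning.
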