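# Methods

## Outcome definition

Lymphopenia is graded from the post-radiotherapy absolute lymphocyte count
(cells/µL) per CTCAE v4.0: grade 0 at or above the laboratory lower limit
of normal (LLN), grade 1 in [800, LLN), grade 2 in [500, 800), grade 3 in
[200, 500), grade 4 below 200. All models use the binary endpoint
grade ≥ 1. The LLN is a laboratory convention, not a universal constant;
the default is 1000/µL (1.0×10⁹/L) and it is configurable everywhere.
Grades 2–4 are exposed but unused downstream. Blood counts reported in
10⁹/L are converted to per-µL by ×1000 before grading.

## Synthetic cohort generator

The generator emulates the structure of a breast-cancer adjuvant
radiotherapy cohort of 589 patients with 57.7% lymphopenia events and an
independent 203-patient validation cohort. It is the test bed for every
downstream stage: because the outcome is drawn from a known logistic
model, attribution sign and rank recovery can be checked against truth.

* **Continuous features** are lognormal, moment-matched to published
  median/quartile triples (μ = log median, σ = (log q3 − log q1)/1.349):
  positive-valued, right-skewed analytes and dose metrics.
* **Dose metrics** share a latent "irradiation extent": each metric's
  log-scale z-score is `λ·L + √(1−λ²)·ε` with loading λ = 0.75, giving
  pairwise latent correlations ≈ 0.56 and, after the lognormal transform,
  pairwise Pearson correlations comfortably above the 0.18 floor the
  cohort structure requires. The log-sd of each dose metric is capped at
  1.0: the two heart metrics have published quartile spans so wide
  (e.g. 4.5–42 Gy) that an uncapped lognormal's heavy tails would push
  their Pearson correlations with other metrics below the floor. The cap
  trades a little marginal fidelity for the contracted correlation
  structure.
* **Per-patient DVH samples**: each metric also gets a per-patient
  irradiated volume, log-linearly coupled to its dose with a per-metric
  sign; exactly one metric (mean heart dose) has a negative volume–dose
  link, reproducing the clinically familiar pattern that high mean heart
  doses come from small tangential fields.
* **Categoricals** are drawn independently from published marginal level
  proportions. Dependencies between categorical features are not modeled
  (no joint distribution is available to emulate), so tests passing on
  synthetic data say nothing about real-world confounding among, e.g.,
  surgery type and nodal stage.
* **Outcome**: linear predictor on standardized continuous features and
  raw 0/1 indicators with a signed effect vector (defaults: strong
  protection from baseline lymphocytes −1.2 per SD, promotion from
  integral body dose +0.9, lung V5s +0.5, chemotherapy regimen ±,
  etc.); the intercept is calibrated by bisection (tolerance 1e-4 on the
  mean response; deterministic and derivative-free) to hit the target
  event rate, then outcomes are Bernoulli draws. Post-RT lymphocyte
  counts are drawn from a truncated lognormal on the side of the LLN the
  outcome dictates, so grading the generated counts reproduces the
  generated outcome exactly.
* **Missingness** is injected completely at random, on continuous
  features only (default 3%). No informative-missingness mechanism is
  modeled.

What the generator does **not** emulate: longitudinal blood-count
trajectories, fractionation schedules, within-group categorical
dependence, measurement error in DVH extraction, or cohort drift between
testing and validation populations. Passing tests demonstrate estimator
correctness and sign/rank recovery under the planted model, not clinical
validity on real data.

## Univariate screen

One logistic regression per feature. Binary contrasts are fitted by
maximum likelihood on the four frequency-weighted cells, so the odds
ratio equals the closed-form cross-product ratio ad/bc; Wald intervals on
the log scale. Complete separation (a zero cell) is flagged and reported
with non-finite Wald limits rather than corrected (no Firth penalty):
degenerate rows should look degenerate. Continuous odds ratios are per
unit on the native scale. The Bonferroni multiplier m is the number of
tests actually performed in the run and is recorded in the output table;
published adjusted p-values imply m ≈ 47 there, and no attempt is made to
match another study's m beyond that consistency check.

## Bootstrap × cross-validation engine

Each of B iterations (default 100) draws floor(0.8·n) patients **without
replacement** (the procedure is conventionally called bootstrapping, but
an 80% subsample is what is described; a with-replacement flag exists),
splits floor(0.7·draw) into training with outcome stratification (avoids
single-class test sets), and assigns stratified tenfold CV on the
training set. Per-iteration seeds derive from one root seed via
`SeedSequence.spawn`, so identical seed + config ⇒ identical outputs.

The XGBoost grid is the stated one (learning_rate 0.01–0.1 step 0.01,
gamma 0–5, max_depth 3–6, scale_pos_weight 1–2 step 0.2, subsample and
colsample_bytree 0.7–1 step 0.1, min_child_weight 3–6, max_delta_step
0–5; 552,960 points). Searching it exhaustively inside every iteration is
out of proportion to any desk-scale run, so three modes exist: `fast`
(the published final configuration: learning_rate 0.04, gamma 5,
max_depth 3, scale_pos_weight 1.8, subsample 0.8, colsample_bytree 0.7,
min_child_weight 5, max_delta_step 1), `random` (200 sampled
configurations plus the published one, re-tuned per iteration), and
`full`. Ties break toward lower max_depth, then lower learning rate, then
first seen. Boosting rounds are fixed at 200 (no early stopping is part
of the procedure); the classification threshold for the thresholded
metrics is 0.5, configurable.

Tree models train on all rows, using native missing-value routing.
The L1-penalized logistic regression standardizes features internally
(penalty fairness; trees are scale-invariant so their inputs stay raw)
and uses complete cases only; its penalty is chosen to maximize
cross-validated ROC-AUC over a log-spaced path (the published description
of the penalty selection is not interpretable as written; CV-AUC
maximization is this package's reading), with ties toward the stronger
penalty. Zero coefficients are recorded as not selected; p-values come
from an unpenalized refit on the selected support — a pragmatic
Table-layout convention, not valid post-selection inference, and they
should be read as descriptive.

ROC-AUC is the trapezoidal area under the empirical ROC; PR-AUC is
step-interpolated average precision. Single-class evaluation sets yield
missing AUCs rather than errors.

## Attribution statistics

Per-instance attributions are exact tree-path (TreeSHAP) values computed
natively by XGBoost on the raw log-odds margin, where additivity is exact;
local accuracy (base value + row sum = margin prediction) is asserted at
1e-4 on every call by default. Attributions are computed on each
iteration's **test set**: attributing memorized training noise would
inflate importance. A flag switches to the training set.

Importance is mean |SHAP| over instances within an iteration, then over
iterations. Direction is, per iteration, the Spearman rank correlation
(average-rank ties) of a feature's attribution column against a target,
averaged over iterations; constant columns contribute 0 so the mean stays
defined. Two targets are supported:

* **feature values** (package default): a protective feature — high
  values pushing the margin down — scores near −1; this is the scale on
  which published direction tables report strongly negative protective
  features, and the only variant that can recover a planted effect's sign.
* **outcomes** (the literal variant, `direction_score`'s own default):
  necessarily non-negative for any feature the model genuinely uses,
  since event patients receive the largest attribution pushes; it is kept
  as a diagnostic of attribution–outcome concordance.

Features never used by any model have zero importance and direction 0 by
convention. The contribution graph (GraphML) has one node per feature
with nonzero importance, sized by importance, and an edge to the outcome
node weighted by |direction| and signed by its sign.

## Dose-volume analysis

Each dosimetric metric contributes one point: its representative dose and
volume from the catalog and its mean |SHAP|. (A per-patient summary
statistic is not dictated anywhere; the catalog's nominal values are
medians, and the choice is configurable in spirit — the regressions are
agnostic to how the point was summarized.) Two OLS fits: log10(volume)
and log2(dose) on importance, with two-sided slope p-values. Volumes in
mixed units (% organ vs litres) are used as given after the log
transform, with a logged warning — the mixture shifts intercepts, not the
rank structure. The volume–dose profile computes each metric's Pearson
correlation across patients and flags negative-link (heart-like) metrics,
excluding them from monotonicity claims. Interpretive statements (e.g.
lymphocyte sensitivity below 4 Gy) are emitted as annotation only; tests
assert only computed quantities.

## Matched-pair validation

For a probe feature, the important set is every feature with importance
strictly greater than the probe's (the probe never matches on itself).
Discrepancy between two patients is the mean over important features of
|f_a − f_b| / f_max, with f_max the per-feature maximum over the analysis
cohort, recomputed per cohort. Categorical features enter through their
0/1 indicator columns (f_max = 1). Candidate pairs are all
discordant-outcome pairs with discrepancy strictly below the threshold
(default 0.10 — deliberately tight; no published value exists); selection
is greedy in ascending discrepancy with deterministic identifier
tie-breaks and no patient reuse. Pairs missing an important-feature value
are ineligible. The paired t-test is two-sided on (value in the event
member − value in the non-event member); zero-variance differences are
flagged degenerate rather than tested. Pairing is run one probe at a
time with a refreshed importance set per probe.

## Pipeline and reproducibility

Stages communicate only through files in one output directory; every CSV
begins with a `# radlymph seed=<seed> config=<hash>` stamp (read with
`comment="#"`), where the hash covers the scientific configuration but
not the output path. Two runs with the same seed are byte-identical.
XGBoost runs single-threaded with fixed seeds for determinism.

## Problem sizes in tests

The default test suite runs the engine at reduced scale chosen to
exercise every code path at trustworthy statistical power: cohorts of
200–589 patients, B = 2–20 iterations with the fast-path configuration,
10 replicate runs for sign-recovery checks, 10,000-replicate Monte-Carlo
nulls for the scalar statistics (Bonferroni family-wise error, paired-t
type-I error), and 200-replicate coverage checks for the dose-volume
slopes. These sizes are the package's own test design; the library's
defaults (B = 100, randomized 200-point searches) are what an analysis
run would use.

## Known limitations

* The synthetic generator's categorical independence and MCAR
  missingness are simplifications; effect estimates on real cohorts will
  face confounding the tests never see.
* Lasso p-values are post-selection refits, not honest inference.
* The direction score is a rank correlation of attributions, not a causal
  effect sign; collinear dose metrics can carry each other's direction
  (the heart metrics exemplify this, which is exactly what the
  matched-pair stage is for).
* No calibration, decision-curve, or survival analyses; no DVH extraction
  from treatment-planning systems (tabular DVH summaries are consumed as
  given); no effective-dose-to-immune-cells modeling.
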