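# radlymph

Interpretable machine-learning analysis of **radiation-induced lymphopenia**
in tabular oncology cohorts — for radiation oncology researchers and
biostatisticians who want the full chain from cohort table to directional
feature attributions as a tested, reproducible library.

Radiation-induced lymphopenia (CTCAE v4.0 grade ≥ 1: a post-radiotherapy
absolute lymphocyte count below the laboratory lower limit of normal) is a
common toxicity of breast-cancer radiotherapy with prognostic significance.
The package implements an analysis pipeline for its potential determinants:

* **Synthetic cohort generator** — emulates a 589-patient adjuvant
  radiotherapy cohort (57.7% events): five feature groups, lognormal blood
  counts, multicollinear DVH dose metrics driven by a shared latent
  irradiation extent (pairwise Pearson r ≥ 0.18), one heart-dose metric
  whose irradiated volume *shrinks* as dose grows, and a binary outcome from
  a logistic model with planted, known effect directions.
* **Preprocessing** — CTCAE grading, dummy encoding against designated
  reference levels, five named group views (clinical, tumor, blood,
  radiotherapy, treatment).
* **Univariate screen** — per-feature logistic odds ratios with Wald 95%
  CIs and Bonferroni-adjusted p-values; for a binary contrast the MLE odds
  ratio equals the 2×2 cross-product ratio ad/bc.
* **Bootstrap × CV modeling** — B iterations (default 100) of 80% draws,
  stratified 7:3 train/test splits, tenfold CV; XGBoost tuned over the
  stated 552,960-point hyperparameter grid (randomized search, with a
  published fast-path configuration) and L1-penalized logistic regression
  with a CV-AUC-tuned penalty on complete cases; six metrics (sensitivity,
  specificity, accuracy, F1, ROC-AUC, PR-AUC) on test and external
  validation cohorts, for the full model and per feature group.
* **Directional SHAP attribution** — exact tree-path (TreeSHAP) per-instance
  attributions on the log-odds margin; importance = mean |SHAP| over
  instances then iterations; **direction ∈ [−1, 1]** = mean over iterations
  of the Spearman correlation of each feature's attribution column
  (against its own values by default; against outcomes as the literal
  variant) — near +1 promotes lymphopenia, near −1 protects.
* **Dose-volume regressions** — per dosimetric metric, one
  (dose, volume, importance) point; OLS of log10(volume) and log2(dose) on
  importance, plus per-metric volume–dose correlation profiling that flags
  heart-like negative-link metrics.
* **Matched-pair validation** — pairs of patients with discordant outcomes
  and discrepancy `(1/n) Σ |f_a − f_b| / f_max < threshold` over the
  features more important than a probe; paired t-test of the probe.

## Worked example

```bash
python examples/03_train_attribute.py
```

runs five bootstrap iterations on a seeded synthetic cohort and prints:

```
test-set ROC-AUC across iterations (median, quartiles):
  median       q1       q3
0.792137 0.784254 0.815271

top contributions (importance + direction):
                            mean_abs_shap  direction
baseline_lymphocytes                0.622     -0.921
integral_body_dose                  0.383      0.893
v5_bilateral_lung                   0.336      0.749
v5_ipsilateral_lung                 0.232      0.941
...
planted effects, for comparison:
  baseline_lymphocytes       -1.20
  integral_body_dose         +0.90
  v5_bilateral_lung          +0.55
```

The ROC-AUC ≈ 0.79 says the boosted model separates lymphopenia cases well
on held-out patients. The attribution table recovers the planted truth: the
strongest planted effect (baseline lymphocytes, log-odds −1.2 per SD) ranks
first in mean |SHAP| with a strongly negative direction (protective), while
whole-body irradiation extent ranks next with a positive direction
(promoting). The other examples cover simulation (`01`), univariate
screening against published counts (`02`), dose-volume regressions (`04`)
and matched-pair probing of the mean heart dose (`05`).

A thin CLI wraps the same pipeline:

```bash
radlymph all --outdir run1 --seed 1 -B 10
```

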