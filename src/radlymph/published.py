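"""Published summary statistics of a breast-cancer radiotherapy cohort.

A 589-patient testing cohort (340 lymphopenia events, 57.7%) and a
203-patient independent validation cohort (104 events, 51.2%). The 2x2
contingency counts below are the univariate screen inputs: for each
categorical risk factor, counts of patients (without-event, with-event)
at the reference level and at a contrast level. These counts are inputs
to the odds-ratio computations; the printed odds ratios serve as checks.

Continuous summaries (median and quartiles) parameterize the synthetic
cohort generator's marginal distributions.
"""

from __future__ import annotations

TESTING_N = 589
TESTING_EVENTS = 340
VALIDATION_N = 203
VALIDATION_EVENTS = 104

# (feature, level, ref_counts, level_counts, printed_or)
# counts are (n_without_event, n_with_event); printed_or is the published
# univariate odds ratio for the contrast level vs the reference level.
CONTINGENCY_TABLES = [
    ("rt_fields", "regional_lymphatics", (133, 80), (116, 260), 3.73),
    ("rt_dose", "more_than_50gy_25fx", (241, 290), (8, 50), 5.19),
    ("modified_n_stage", "more_than_0", (135, 89), (114, 251), 3.34),
    ("surgery", "mrm", (151, 135), (98, 205), 2.34),
    ("axillary_surgery", "alnd", (127, 77), (122, 263), 3.56),
    ("electron_boost", "10gy_5fx", (92, 196), (137, 129), 0.44),
    ("chemo_regimen", "anthracycline_taxane", (45, 28), (122, 251), 3.31),
    ("modified_stage", "III", (96, 55), (36, 136), 6.59),
    ("chemo_strategy", "neoadjuvant", (41, 17), (26, 78), 7.24),
]

# Published adjusted p-value pair used to recover the Bonferroni test count:
# baseline platelet p=0.003 adjusted to 0.14 implies m ~ 47 tests.
PLATELET_P = 0.003
PLATELET_P_ADJUSTED = 0.14

# Marginal (pooled over outcome classes) median and quartiles of the
# continuous features, used for moment-matched lognormal generation.
# Units: blood counts 1e9/L except hemoglobin g/L; doses Gy; Vx percent
# organ volume; age years; tumor size cm; Ki67 percent.
CONTINUOUS_SUMMARIES = {
    "age": (45.0, 39.0, 51.0),
    "tumor_size": (2.0, 1.3, 2.6),
    "ki67": (30.0, 15.0, 40.0),
    "baseline_wbc": (5.2, 4.2, 6.4),
    "baseline_hemoglobin": (118.0, 110.0, 126.0),
    "baseline_platelets": (234.0, 196.0, 276.0),
    "baseline_neutrophils": (3.2, 2.4, 4.2),
    "baseline_lymphocytes": (1.53, 1.20, 1.86),
    "baseline_monocytes": (0.31, 0.24, 0.39),
    "integral_body_dose": (4.0, 3.3, 5.0),
    "mean_heart_dose": (2.1, 0.5, 3.7),
    "max_heart_dose": (39.8, 4.5, 42.0),
    "v20_ipsilateral_lung": (20.9, 15.9, 25.8),
    "v5_ipsilateral_lung": (38.4, 29.0, 52.0),
    "mean_ipsilateral_lung_dose": (10.4, 7.8, 12.4),
    "v20_bilateral_lung": (10.1, 7.5, 13.0),
    "v5_bilateral_lung": (19.5, 14.3, 31.0),
    "mean_bilateral_lung_dose": (5.3, 3.9, 7.0),
}

# Post-radiotherapy lymphocyte count summary (per uL): 950 (750-1170).
POST_RT_LYMPHOCYTES = (950.0, 750.0, 1170.0)

# Marginal level counts of the categorical features (pooled classes, n=589),
# reference level listed first, matching the published cohort table layout.
CATEGORICAL_MARGINALS = {
    "family_history": [("without", 385), ("with", 204)],
    "smoking_history": [("without", 432), ("with", 3), ("unknown", 154)],
    "drinking_history": [("without", 432), ("with", 3), ("unknown", 154)],
    "menopausal": [
        ("premenopausal", 395),
        ("perimenopausal", 39),
        ("postmenopausal", 155),
    ],
    "modified_n_stage": [("0", 224), ("more_than_0", 365)],
    "modified_stage": [("I", 151), ("II", 266), ("III", 172)],
    "tumor_side": [("left", 298), ("right", 291)],
    "er": [("negative", 163), ("positive", 426)],
    "pr": [("negative", 213), ("positive", 376)],
    "her2": [("negative", 435), ("positive", 154)],
    "ihc": [
        ("hr_pos_her2_neg", 346),
        ("hr_neg_her2_pos", 64),
        ("hr_pos_her2_pos", 91),
        ("hr_neg_her2_neg", 88),
    ],
    "rt_technique": [("rapidarc", 100), ("2d_fields", 211), ("3d_fields", 278)],
    "electron_boost": [("none", 288), ("10gy_5fx", 266), ("16gy_8fx", 35)],
    "rt_fields": [("tangential_breast_only", 213), ("regional_lymphatics", 376)],
    "rt_dose": [("40.5gy_15fx", 531), ("more_than_50gy_25fx", 58)],
    "surgery": [("bct", 286), ("mrm", 303)],
    "axillary_surgery": [("slnb", 204), ("alnd", 385)],
    "margin": [("clear", 561), ("close_or_positive", 28)],
    "chemo_strategy": [
        ("none", 58),
        ("neoadjuvant", 104),
        ("adjuvant", 413),
        ("neoadjuvant_adjuvant", 14),
    ],
    "chemo_regimen": [
        ("others", 73),
        ("taxane", 143),
        ("anthracycline_taxane", 373),
    ],
    "anti_her2": [("without", 442), ("with", 147)],
    "endocrine": [("without", 152), ("with", 437)],
}
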