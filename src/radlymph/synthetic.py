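"""Synthetic breast-cancer radiotherapy cohorts with planted ground truth.

The generator emulates the structure of a 589-patient adjuvant-radiotherapy
cohort: five feature groups (clinical, tumor, blood, radiotherapy,
treatment), right-skewed blood counts, multicollinear dosimetric features
driven by a shared latent "irradiation extent", one heart-dose metric whose
irradiated volume shrinks as its dose grows, categorical treatment
variables drawn from published marginal proportions, and a binary
lymphopenia outcome from a logistic model on standardized features with a
user-chosen signed effect vector. The intercept is calibrated by bisection
so the mean event probability hits a target rate (default 57.7%).

Because the effect vector is known, downstream importance and direction
statistics can be tested for sign and rank recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from radlymph import published
from radlymph.preprocess import (
    DEFAULT_LLN,
    FeatureSchema,
    FeatureSpec,
    grade_lymphopenia,
)

# Normal quartile: q1/q3 of a lognormal sit at exp(mu -/+ 0.6745 sigma).
_Z75 = 0.6744897501960817


class CalibrationError(RuntimeError):
    """Raised when no intercept can reach the requested event rate."""


@dataclass(frozen=True)
class DoseMetricSpec:
    """One dosimetric feature: nominal dose level, irradiated volume, and
    the sign of the volume-dose link across patients (+1 for the usual
    'bigger field, more dose' pattern, -1 for heart-like metrics)."""

    name: str
    dose_gy: float
    volume: float
    volume_dose_sign: int = 1

    def __post_init__(self) -> None:
        if self.dose_gy <= 0 or self.volume <= 0:
            raise ValueError(f"dose and volume must be positive for {self.name!r}")
        if self.volume_dose_sign not in (-1, 1):
            raise ValueError("volume_dose_sign must be +1 or -1")


@dataclass
class GeneratorConfig:
    n_patients: int = 589
    event_rate_target: float = published.TESTING_EVENTS / published.TESTING_N
    #: feature (or "feature=level" indicator) -> log-odds per standardized unit
    effect_vector: dict[str, float] = field(default_factory=dict)
    dose_metric_spec: list[DoseMetricSpec] = field(default_factory=list)
    #: analyte -> (log-mean, log-sd)
    blood_count_params: dict[str, tuple[float, float]] = field(default_factory=dict)
    missingness_rate: float = 0.0
    seed: int = 0
    #: shared-latent loading of each dose metric (pairwise Pearson ~ loading^2)
    dose_latent_loading: float = 0.75
    #: minimum pairwise dose-metric correlation the generator aims to exceed
    correlation_floor: float = 0.18
    lower_limit_normal: float = DEFAULT_LLN

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not 0.0 < self.event_rate_target < 1.0:
            raise ValueError("event_rate_target must lie strictly in (0, 1)")
        if not 0.0 <= self.missingness_rate < 1.0:
            raise ValueError("missingness_rate must lie in [0, 1)")
        for k, v in self.effect_vector.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite effect for {k!r}")
        names = [m.name for m in self.dose_metric_spec]
        if len(set(names)) != len(names):
            raise ValueError("duplicate dose metric names")
        if not 0.0 < self.dose_latent_loading < 1.0:
            raise ValueError("dose_latent_loading must lie in (0, 1)")


@dataclass
class GroundTruth:
    """Planted truth behind a generated cohort."""

    effect_vector: dict[str, float]
    linear_predictor: np.ndarray
    intercept: float
    event_rate_target: float
    realized_event_rate: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "effect_vector": self.effect_vector,
                    "intercept": self.intercept,
                    "event_rate_target": self.event_rate_target,
                    "realized_event_rate": self.realized_event_rate,
                    "linear_predictor": [float(v) for v in self.linear_predictor],
                },
                fh,
                indent=2,
            )


@dataclass
class DoseMetricCatalog:
    """Per-metric representative (dose, volume) pairs, optionally with
    per-patient DVH-style samples for the volume-dose profiling step."""

    table: pd.DataFrame  # columns: metric, dose_gy, volume, volume_dose_sign
    dvh_samples: pd.DataFrame | None = None  # patient_id, metric, dose, volume

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DoseMetricCatalog":
        return cls(pd.read_csv(path))


def _lognormal_params(median: float, q1: float, q3: float) -> tuple[float, float]:
    """Moment-match a lognormal to a (median, q1, q3) triple."""
    mu = np.log(median)
    sigma = (np.log(q3) - np.log(q1)) / (2.0 * _Z75)
    return mu, sigma


DEFAULT_DOSE_METRICS = [
    DoseMetricSpec("integral_body_dose", 4.0, 30.0, 1),
    DoseMetricSpec("v5_bilateral_lung", 5.0, 19.5, 1),
    DoseMetricSpec("v5_ipsilateral_lung", 5.0, 38.4, 1),
    DoseMetricSpec("mean_bilateral_lung_dose", 5.3, 3.2, 1),
    DoseMetricSpec("mean_ipsilateral_lung_dose", 10.4, 1.7, 1),
    DoseMetricSpec("v20_ipsilateral_lung", 20.0, 20.9, 1),
    DoseMetricSpec("v20_bilateral_lung", 20.0, 10.1, 1),
    DoseMetricSpec("mean_heart_dose", 2.1, 0.65, -1),
    DoseMetricSpec("max_heart_dose", 39.8, 0.01, 1),
]

#: Planted signed effects (log-odds per SD for continuous features, per
#: indicator for categorical levels). Strong protection from baseline
#: lymphocytes and strong promotion from whole-body irradiation extent
#: mirror the qualitative structure the analysis is meant to recover.
DEFAULT_EFFECTS = {
    "baseline_lymphocytes": -1.2,
    "integral_body_dose": 0.9,
    "v5_bilateral_lung": 0.55,
    "v5_ipsilateral_lung": 0.5,
    "baseline_wbc": -0.3,
    "mean_bilateral_lung_dose": 0.3,
    "baseline_platelets": -0.3,
    "baseline_monocytes": -0.25,
    "baseline_hemoglobin": 0.2,
    "mean_heart_dose": -0.2,
    "chemo_regimen=anthracycline_taxane": 0.5,
    "chemo_regimen=taxane": -0.3,
    "rt_fields=regional_lymphatics": 0.3,
}

_BLOOD_ANALYTES = (
    "baseline_wbc",
    "baseline_hemoglobin",
    "baseline_platelets",
    "baseline_neutrophils",
    "baseline_lymphocytes",
    "baseline_monocytes",
)

_OTHER_CONTINUOUS = ("age", "tumor_size", "ki67")


def default_schema(dose_metrics: Sequence[DoseMetricSpec] | None = None) -> FeatureSchema:
    """Schema of the emulated cohort: five groups, published level sets."""
    dose_metrics = list(dose_metrics or DEFAULT_DOSE_METRICS)
    cat = published.CATEGORICAL_MARGINALS

    def cat_spec(name: str, group: str) -> FeatureSpec:
        return FeatureSpec(name, group, "categorical", tuple(l for l, _ in cat[name]))

    features = [
        FeatureSpec("age", "clinical", "continuous", units="years"),
        cat_spec("family_history", "clinical"),
        cat_spec("smoking_history", "clinical"),
        cat_spec("drinking_history", "clinical"),
        cat_spec("menopausal", "clinical"),
        cat_spec("modified_n_stage", "tumor"),
        cat_spec("modified_stage", "tumor"),
        cat_spec("tumor_side", "tumor"),
        FeatureSpec("tumor_size", "tumor", "continuous", units="cm"),
        cat_spec("er", "tumor"),
        cat_spec("pr", "tumor"),
        cat_spec("her2", "tumor"),
        cat_spec("ihc", "tumor"),
        FeatureSpec("ki67", "tumor", "continuous", units="%"),
        FeatureSpec("baseline_wbc", "blood", "continuous", units="1e9/L"),
        FeatureSpec("baseline_hemoglobin", "blood", "continuous", units="g/L"),
        FeatureSpec("baseline_platelets", "blood", "continuous", units="1e9/L"),
        FeatureSpec("baseline_neutrophils", "blood", "continuous", units="1e9/L"),
        FeatureSpec("baseline_lymphocytes", "blood", "continuous", units="1e9/L"),
        FeatureSpec("baseline_monocytes", "blood", "continuous", units="1e9/L"),
    ]
    for m in dose_metrics:
        features.append(FeatureSpec(m.name, "radiotherapy", "continuous", units="Gy or %"))
    features += [
        cat_spec("rt_technique", "radiotherapy"),
        cat_spec("electron_boost", "radiotherapy"),
        cat_spec("rt_fields", "radiotherapy"),
        cat_spec("rt_dose", "radiotherapy"),
        cat_spec("surgery", "treatment"),
        cat_spec("axillary_surgery", "treatment"),
        cat_spec("margin", "treatment"),
        cat_spec("chemo_strategy", "treatment"),
        cat_spec("chemo_regimen", "treatment"),
        cat_spec("anti_her2", "treatment"),
        cat_spec("endocrine", "treatment"),
    ]
    return FeatureSchema(features)


def default_config(
    n_patients: int = 589,
    seed: int = 0,
    missingness_rate: float = 0.03,
    effect_vector: Mapping[str, float] | None = None,
    event_rate_target: float | None = None,
) -> GeneratorConfig:
    """The study conditions: n=589, 57.7% events, default planted effects."""
    blood = {
        a: _lognormal_params(*published.CONTINUOUS_SUMMARIES[a]) for a in _BLOOD_ANALYTES
    }
    return GeneratorConfig(
        n_patients=n_patients,
        event_rate_target=(
            published.TESTING_EVENTS / published.TESTING_N
            if event_rate_target is None
            else event_rate_target
        ),
        effect_vector=dict(DEFAULT_EFFECTS if effect_vector is None else effect_vector),
        dose_metric_spec=list(DEFAULT_DOSE_METRICS),
        blood_count_params=blood,
        missingness_rate=missingness_rate,
        seed=seed,
    )


def _calibrate_intercept(eta: np.ndarray, target: float, tol: float = 1e-4) -> float:
    """Bisection on c so that mean(expit(eta + c)) = target."""

    def rate(c: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(eta + c)))))

    lo, hi = -40.0, 40.0
    if rate(lo) > target or rate(hi) < target:
        raise CalibrationError(
            f"event rate {target} unattainable for the given effects"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        r = rate(mid)
        if abs(r - target) < tol:
            return mid
        if r < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _sample_categoricals(schema: FeatureSchema, n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    out = {}
    for f in schema:
        if f.kind != "categorical":
            continue
        counts = dict(published.CATEGORICAL_MARGINALS[f.name])
        probs = np.array([counts[lv] for lv in f.levels], dtype=float)
        probs /= probs.sum()
        out[f.name] = rng.choice(np.array(f.levels, dtype=object), size=n, p=probs)
    return out


def _truncated_lognormal(
    rng: np.random.Generator, mu: float, sigma: float, lo: float, hi: float, size: int
) -> np.ndarray:
    """Inverse-CDF sampling of a lognormal restricted to [lo, hi)."""
    from scipy.stats import lognorm

    dist = lognorm(s=sigma, scale=np.exp(mu))
    a, b = dist.cdf(lo), dist.cdf(hi)
    u = rng.uniform(a, b, size=size)
    return dist.ppf(u)


def generate_dose_catalog(config: GeneratorConfig) -> DoseMetricCatalog:
    """Emit the per-metric representative (dose, volume) catalog."""
    if not config.dose_metric_spec:
        raise ValueError("dose_metric_spec must be non-empty")
    table = pd.DataFrame(
        {
            "metric": [m.name for m in config.dose_metric_spec],
            "dose_gy": [m.dose_gy for m in config.dose_metric_spec],
            "volume": [m.volume for m in config.dose_metric_spec],
            "volume_dose_sign": [m.volume_dose_sign for m in config.dose_metric_spec],
        }
    )
    return DoseMetricCatalog(table)


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, DoseMetricCatalog, GroundTruth]:
    """Generate a cohort table, its dose catalog with DVH samples, and truth.

    Returns a DataFrame (one row per patient, ``patient_id`` index,
    categorical features as strings, missing as NaN) with pre-/post-
    radiotherapy lymphocyte counts (per uL) and the binary ``lymphopenia``
    outcome, the dose-metric catalog carrying per-patient (dose, volume)
    samples, and the realized :class:`GroundTruth`.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    schema = default_schema(config.dose_metric_spec or DEFAULT_DOSE_METRICS)
    dose_metrics = list(config.dose_metric_spec or DEFAULT_DOSE_METRICS)
    known = set(schema.names) | set(schema.encoded_columns())
    unknown = [k for k in config.effect_vector if k not in known]
    if unknown:
        raise ValueError(f"effect_vector names unknown features: {unknown}")

    cols: dict[str, np.ndarray] = {}

    # clinical / tumor / blood continuous features: independent lognormals
    for name in _OTHER_CONTINUOUS:
        mu, sigma = _lognormal_params(*published.CONTINUOUS_SUMMARIES[name])
        cols[name] = np.exp(rng.normal(mu, sigma, size=n))
    blood_params = config.blood_count_params or {
        a: _lognormal_params(*published.CONTINUOUS_SUMMARIES[a]) for a in _BLOOD_ANALYTES
    }
    for name in _BLOOD_ANALYTES:
        mu, sigma = blood_params[name]
        cols[name] = np.exp(rng.normal(mu, sigma, size=n))

    # dosimetric features: shared latent irradiation extent -> collinearity
    lam = config.dose_latent_loading
    latent = rng.normal(size=n)
    z_dose: dict[str, np.ndarray] = {}
    for m in dose_metrics:
        z = lam * latent + np.sqrt(1.0 - lam * lam) * rng.normal(size=n)
        z_dose[m.name] = z
        if m.name in published.CONTINUOUS_SUMMARIES:
            mu, sigma = _lognormal_params(*published.CONTINUOUS_SUMMARIES[m.name])
        else:
            mu, sigma = np.log(m.dose_gy), 0.35
        # cap the log-sd: heavier tails than this break the Pearson
        # correlation floor the dose metrics are contracted to keep
        cols[m.name] = np.exp(mu + min(sigma, 1.0) * z)

    cols.update(_sample_categoricals(schema, n, rng))

    # per-patient DVH samples: dose = the feature value; volume follows the
    # metric's nominal volume with a signed log-linear link to the dose
    dvh_rows = []
    for m in dose_metrics:
        vol = m.volume * np.exp(
            m.volume_dose_sign * 0.6 * z_dose[m.name] + 0.2 * rng.normal(size=n)
        )
        dvh_rows.append(
            pd.DataFrame(
                {
                    "patient_id": np.arange(n),
                    "metric": m.name,
                    "dose": cols[m.name],
                    "volume": vol,
                }
            )
        )
    dvh = pd.concat(dvh_rows, ignore_index=True)

    # linear predictor on standardized continuous features / raw indicators
    eta = np.zeros(n)
    realized: dict[str, float] = {}
    for key, beta in config.effect_vector.items():
        if beta == 0.0:
            continue
        if "=" in key:
            feature, level = key.split("=", 1)
            x = (cols[feature] == level).astype(float)
        else:
            raw = cols[key]
            x = (raw - raw.mean()) / raw.std()
        eta += beta * x
        realized[key] = float(beta)

    intercept = _calibrate_intercept(eta, config.event_rate_target)
    prob = 1.0 / (1.0 + np.exp(-(eta + intercept)))
    outcome = (rng.uniform(size=n) < prob).astype(int)

    # post-RT lymphocyte count drawn consistently with the outcome grade
    mu_post, sigma_post = _lognormal_params(*published.POST_RT_LYMPHOCYTES)
    lln = config.lower_limit_normal
    post = np.empty(n)
    n_event = int(outcome.sum())
    post[outcome == 1] = _truncated_lognormal(rng, mu_post, sigma_post, 1.0, lln, n_event)
    post[outcome == 0] = _truncated_lognormal(
        rng, mu_post, sigma_post, lln, np.inf, n - n_event
    )

    df = pd.DataFrame(cols)
    df.index.name = "patient_id"
    df["pre_rt_lymphocytes"] = df["baseline_lymphocytes"] * 1000.0
    df["post_rt_lymphocytes"] = post
    df["lymphopenia"] = outcome
    assert np.array_equal(
        (np.asarray(grade_lymphopenia(post, lln)) >= 1).astype(int), outcome
    )

    # MCAR missingness on continuous features only (outcome plumbing intact)
    if config.missingness_rate > 0:
        for name in schema.continuous():
            mask = rng.uniform(size=n) < config.missingness_rate
            df.loc[mask, name] = np.nan

    catalog = DoseMetricCatalog(
        pd.DataFrame(
            {
                "metric": [m.name for m in dose_metrics],
                "dose_gy": [m.dose_gy for m in dose_metrics],
                "volume": [m.volume for m in dose_metrics],
                "volume_dose_sign": [m.volume_dose_sign for m in dose_metrics],
            }
        ),
        dvh_samples=dvh,
    )
    truth = GroundTruth(
        effect_vector=realized,
        linear_predictor=eta,
        intercept=intercept,
        event_rate_target=config.event_rate_target,
        realized_event_rate=float(outcome.mean()),
    )
    return df, catalog, truth


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Write a cohort as CSV: one row per patient, empty cell = missing."""
    cohort.to_csv(path, na_rep="")


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="patient_id")
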