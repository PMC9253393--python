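"""Dose-volume attribution regressions.

Each dosimetric feature contributes one point: its representative
irradiation dose (Gy), irradiated volume, and importance (mean |SHAP|).
Two ordinary least-squares regressions characterize how attribution
tracks the physical quantities:

* log10(volume) ~ importance — volume rises with attribution;
* log2(dose) ~ importance — dose falls (or rises) with attribution.

A third step profiles the per-metric volume-dose relationship across
patients: most metrics couple volume positively to dose, but heart-like
metrics (irradiated volume shrinking as mean heart dose grows) are
flagged and excluded from monotonicity claims.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import pearsonr

logger = logging.getLogger(__name__)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    p_value: float
    r_squared: float
    stderr: float
    n: int

    def as_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "p_value": self.p_value,
            "r_squared": self.r_squared,
            "stderr": self.stderr,
            "n": self.n,
        }


def _ols(response: np.ndarray, predictor: np.ndarray) -> RegressionResult:
    X = sm.add_constant(np.asarray(predictor, dtype=float))
    fit = sm.OLS(np.asarray(response, dtype=float), X).fit()
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        p_value=float(fit.pvalues[1]),
        r_squared=float(fit.rsquared),
        stderr=float(fit.bse[1]),
        n=int(fit.nobs),
    )


def _check_points(points: pd.DataFrame, value_col: str) -> None:
    required = {value_col, "mean_abs_shap"}
    missing = required - set(points.columns)
    if missing:
        raise ValueError(f"points table lacks columns: {sorted(missing)}")
    if len(points) < 3:
        raise ValueError("need at least 3 metric points to regress")
    if (points[value_col] <= 0).any():
        raise ValueError(f"{value_col} must be positive for the log transform")


def regress_volume_on_attribution(points: pd.DataFrame) -> RegressionResult:
    """OLS of log10(irradiated volume) on per-metric importance."""
    _check_points(points, "volume")
    units = points.get("units")
    if units is not None and units.nunique() > 1:
        logger.warning("mixed volume units across metrics: %s", sorted(units.unique()))
    return _ols(np.log10(points["volume"].to_numpy()), points["mean_abs_shap"].to_numpy())


def regress_dose_on_attribution(points: pd.DataFrame) -> RegressionResult:
    """OLS of log2(irradiation dose) on per-metric importance."""
    _check_points(points, "dose_gy")
    return _ols(np.log2(points["dose_gy"].to_numpy()), points["mean_abs_shap"].to_numpy())


def attribution_points(
    catalog: pd.DataFrame, importance: pd.Series, direction: pd.Series | None = None
) -> pd.DataFrame:
    """Join a dose-metric catalog with attribution summaries.

    One row per metric present in both tables: dose, volume, importance
    and (optionally) direction.
    """
    pts = catalog.set_index("metric")[["dose_gy", "volume"]].copy()
    pts["mean_abs_shap"] = importance.reindex(pts.index)
    pts = pts.dropna(subset=["mean_abs_shap"])
    if direction is not None:
        pts["direction"] = direction.reindex(pts.index)
    return pts.reset_index()


def volume_dose_profile(dvh_samples: pd.DataFrame, min_patients: int = 2) -> pd.DataFrame:
    """Per-metric Pearson correlation of irradiated volume with dose.

    `dvh_samples` is long-form: patient_id, metric, dose, volume. Metrics
    with a negative correlation are flagged heart-like and excluded (with
    a log entry) from monotonic volume-dose claims; constant vectors make
    the correlation undefined and are flagged.
    """
    required = {"metric", "dose", "volume"}
    if required - set(dvh_samples.columns):
        raise ValueError(f"dvh_samples needs columns {sorted(required)}")
    rows = []
    for metric, sub in dvh_samples.groupby("metric", sort=True):
        if len(sub) < min_patients:
            raise ValueError(f"metric {metric!r} has < {min_patients} patients")
        d, v = sub["dose"].to_numpy(float), sub["volume"].to_numpy(float)
        if np.all(d == d[0]) or np.all(v == v[0]):
            rows.append(
                {"metric": metric, "pearson_r": np.nan, "p_value": np.nan,
                 "negative_link": False, "undefined": True}
            )
            continue
        r, p = pearsonr(d, v)
        neg = bool(r < 0)
        if neg:
            logger.info("metric %r flagged heart-like (volume falls with dose)", metric)
        rows.append(
            {"metric": metric, "pearson_r": float(r), "p_value": float(p),
             "negative_link": neg, "undefined": False}
        )
    return pd.DataFrame(rows)


def dose_volume_report(
    catalog: pd.DataFrame,
    importance: pd.Series,
    dvh_samples: pd.DataFrame | None = None,
) -> dict:
    """Bundle the two attribution regressions and the volume-dose profile."""
    pts = attribution_points(catalog, importance)
    report = {
        "volume_regression": regress_volume_on_attribution(pts).as_dict(),
        "dose_regression": regress_dose_on_attribution(pts).as_dict(),
        "n_metrics": int(len(pts)),
    }
    if dvh_samples is not None:
        profile = volume_dose_profile(dvh_samples)
        report["volume_dose_profile"] = profile.to_dict(orient="records")
        report["negative_link_metrics"] = profile.loc[
            profile["negative_link"], "metric"
        ].tolist()
    return report
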