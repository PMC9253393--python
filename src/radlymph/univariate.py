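"""Univariate logistic odds-ratio screening with Bonferroni correction.

One logistic regression per feature against the binary lymphopenia
outcome. For a categorical feature each non-reference level yields one
odds ratio versus the reference level; for a binary contrast the MLE odds
ratio coincides with the 2x2 cross-product ratio ad/bc. Confidence
intervals are Wald intervals on the log-odds scale. Complete separation
(a zero cell) is flagged and the estimate reported as unstable rather
than silently corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from radlymph.preprocess import FeatureSchema


@dataclass
class UnivariateResult:
    feature: str
    level: str | None  # None for continuous (per-unit OR)
    odds_ratio: float
    ci95: tuple[float, float]
    p_value: float
    p_adjusted: float | None = None
    separation: bool = False
    counts: tuple[int, int, int, int] | None = None  # (ref0, ref1, lvl0, lvl1)

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not self.separation:
            if self.odds_ratio <= 0:
                raise ValueError("odds ratio must be positive")
            if not (lo <= self.odds_ratio <= hi):
                raise ValueError("CI must bracket the odds ratio")


def _wald_from_logit(beta: float, se: float, p: float) -> tuple[float, tuple[float, float], float]:
    z = 1.959963984540054
    return float(np.exp(beta)), (float(np.exp(beta - z * se)), float(np.exp(beta + z * se))), float(p)


def odds_ratio_from_counts(ref0: int, ref1: int, lvl0: int, lvl1: int) -> float:
    """Cross-product odds ratio of a 2x2 table (contrast level vs reference).

    Rows are (without event, with event) counts; OR = (lvl1*ref0)/(lvl0*ref1).
    """
    if min(ref0, ref1, lvl0, lvl1) < 0:
        raise ValueError("counts must be non-negative")
    if lvl0 == 0 or ref1 == 0:
        return np.inf
    return (lvl1 * ref0) / (lvl0 * ref1)


def fit_univariate_binary(
    ref_counts: tuple[int, int], level_counts: tuple[int, int]
) -> UnivariateResult:
    """Univariate logistic MLE for a binary contrast given 2x2 counts.

    The model is outcome ~ indicator, fitted by maximum likelihood on the
    four frequency-weighted cells; separation (any zero cell) is flagged
    with non-finite Wald limits.
    """
    ref0, ref1 = ref_counts
    lvl0, lvl1 = level_counts
    counts = (ref0, ref1, lvl0, lvl1)
    if min(counts) == 0:
        or_hat = odds_ratio_from_counts(*counts)
        return UnivariateResult(
            feature="", level="", odds_ratio=or_hat, ci95=(0.0, np.inf),
            p_value=np.nan, separation=True, counts=counts,
        )
    X = sm.add_constant(np.array([0.0, 0.0, 1.0, 1.0]))
    y = np.array([0.0, 1.0, 0.0, 1.0])
    freq = np.array(counts, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=freq).fit()
    or_hat, ci, p = _wald_from_logit(fit.params[1], fit.bse[1], fit.pvalues[1])
    return UnivariateResult(
        feature="", level="", odds_ratio=or_hat, ci95=ci, p_value=p, counts=counts
    )


def fit_univariate(
    outcome: pd.Series | np.ndarray,
    predictor: pd.Series,
    schema: FeatureSchema | None = None,
    feature: str | None = None,
) -> list[UnivariateResult]:
    """Univariate logistic regression of the outcome on one feature.

    Continuous predictors yield one per-unit odds ratio on the native
    scale; categorical predictors yield one result per non-reference level
    (reference = the schema's designated level, else the first observed).
    Rows with a missing predictor are dropped.
    """
    y = pd.Series(np.asarray(outcome), index=predictor.index).astype(float)
    keep = predictor.notna()
    y, x = y[keep], predictor[keep]
    if y.nunique() < 2:
        raise ValueError("outcome must contain both classes")
    name = feature or (predictor.name or "feature")

    if pd.api.types.is_numeric_dtype(x) and x.nunique() > 2:
        X = sm.add_constant(x.to_numpy(dtype=float))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y.to_numpy(), X).fit(disp=False)
        or_hat, ci, p = _wald_from_logit(fit.params[1], fit.bse[1], fit.pvalues[1])
        return [UnivariateResult(name, None, or_hat, ci, p)]

    if schema is not None and feature is not None and feature in schema.names:
        levels = list(schema[feature].levels)
    else:
        levels = sorted(x.astype(str).unique())
    ref = levels[0]
    results = []
    for level in levels[1:]:
        sub = x.astype(str).isin([ref, level])
        ys, xs = y[sub], x[sub].astype(str)
        ref0 = int(((xs == ref) & (ys == 0)).sum())
        ref1 = int(((xs == ref) & (ys == 1)).sum())
        lvl0 = int(((xs == level) & (ys == 0)).sum())
        lvl1 = int(((xs == level) & (ys == 1)).sum())
        if lvl0 + lvl1 == 0:
            continue
        res = fit_univariate_binary((ref0, ref1), (lvl0, lvl1))
        res.feature, res.level = name, level
        results.append(res)
    return results


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, p * m), order-preserving.

    ``m`` defaults to the number of p-values supplied; it may be larger
    (when only a subset of the tests performed is being adjusted) but
    never smaller.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m_eff = len(p) if m is None else int(m)
    if m_eff < len(p):
        raise ValueError("m must cover at least the tests supplied")
    return np.minimum(1.0, p * m_eff)


def implied_bonferroni_m(p: float, p_adjusted: float) -> float:
    """Recover the number of tests implied by a (p, adjusted-p) pair."""
    if p <= 0 or p_adjusted <= 0:
        raise ValueError("p-values must be positive")
    return p_adjusted / p


def screen_cohort(
    cohort: pd.DataFrame,
    schema: FeatureSchema,
    outcome: str = "lymphopenia",
    m: int | None = None,
) -> pd.DataFrame:
    """Full univariate screen: one table row per feature/level contrast.

    The Bonferroni multiplier is the number of tests actually performed
    (recorded in the ``m`` column) unless overridden.
    """
    y = cohort[outcome]
    rows: list[UnivariateResult] = []
    for f in schema:
        rows.extend(fit_univariate(y, cohort[f.name], schema=schema, feature=f.name))
    m_eff = m if m is not None else len(rows)
    finite_p = np.array([r.p_value for r in rows])
    adj = np.where(
        np.isfinite(finite_p), np.minimum(1.0, finite_p * m_eff), np.nan
    )
    records = []
    for r, pa in zip(rows, adj):
        r.p_adjusted = None if np.isnan(pa) else float(pa)
        c = r.counts or (None, None, None, None)
        records.append(
            {
                "feature": r.feature,
                "level": r.level if r.level is not None else "",
                "n_ref_no_event": c[0],
                "n_ref_event": c[1],
                "n_level_no_event": c[2],
                "n_level_event": c[3],
                "odds_ratio": r.odds_ratio,
                "ci_low": r.ci95[0],
                "ci_high": r.ci95[1],
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "separation": r.separation,
                "m": m_eff,
            }
        )
    return pd.DataFrame.from_records(records)
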