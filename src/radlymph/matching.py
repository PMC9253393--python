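"""Discrepancy-matched pairs for proof-of-concept validation.

To probe a feature whose signal may be overshadowed by more important
features, patients are paired across outcomes while holding the more
important features similar. For patients a and b the discrepancy over the
n important features is

    (1/n) * sum_i |f_a,i - f_b,i| / fmax_i,

with fmax_i the feature's maximum over the analysis cohort. Pairs with
discordant lymphopenia outcomes and discrepancy below a threshold are
selected greedily (ascending discrepancy, no patient reuse), and a paired
t-test assesses the probe feature across the matched pairs.

The "important" set for a probe contains exactly the features whose mean
|SHAP| is strictly greater than the probe's, so a probe never matches on
itself. Categorical features participate through their 0/1 indicator
columns (fmax = 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ttest_rel

logger = logging.getLogger(__name__)


@dataclass
class PairedSet:
    probe: str
    important: list[str]
    threshold: float
    #: (patient_with_event, patient_without_event, discrepancy)
    pairs: list[tuple] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(d >= self.threshold for _, _, d in self.pairs):
            raise ValueError("all selected discrepancies must be below threshold")

    def __len__(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.pairs, columns=["patient_event", "patient_no_event", "discrepancy"]
        )


def discrepancy(
    a: pd.Series, b: pd.Series, important: list[str], fmax: pd.Series
) -> float:
    """Mean absolute relative difference over the important features.

    Symmetric in (a, b); zero iff the two patients agree on every
    important feature. NaN (pair ineligible) when either patient is
    missing an important feature.
    """
    if not important:
        raise ValueError("need at least one important feature")
    fm = fmax[important].to_numpy(dtype=float)
    if np.any(fm <= 0):
        bad = [f for f, m in zip(important, fm) if m <= 0]
        raise ValueError(f"non-positive feature maxima for {bad}")
    va = a[important].to_numpy(dtype=float)
    vb = b[important].to_numpy(dtype=float)
    if np.isnan(va).any() or np.isnan(vb).any():
        return np.nan
    return float(np.mean(np.abs(va - vb) / fm))


def important_features(summary: pd.Series | pd.DataFrame, probe: str) -> list[str]:
    """Features whose importance strictly exceeds the probe's."""
    imp = summary["mean_abs_shap"] if isinstance(summary, pd.DataFrame) else summary
    if probe not in imp.index:
        raise ValueError(f"probe {probe!r} absent from the attribution summary")
    return imp.index[imp > imp[probe]].tolist()


def select_pairs(
    X: pd.DataFrame,
    outcome: pd.Series,
    probe: str,
    summary: pd.Series | pd.DataFrame,
    threshold: float = 0.10,
    fmax: pd.Series | None = None,
) -> PairedSet:
    """Select discordant-outcome pairs under the discrepancy threshold.

    `X` is an encoded matrix view (continuous + indicator columns) for the
    analysis cohort; feature maxima default to the column maxima of that
    cohort. Candidates are all (event, non-event) pairs with discrepancy
    strictly below `threshold`; selection is greedy in ascending
    discrepancy with deterministic tie-breaks on patient identifiers, and
    no patient joins more than one pair. An empty result is a warning,
    not an error.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    important = important_features(summary, probe)
    important = [f for f in important if f in X.columns]
    if not important:
        raise ValueError(f"no important features above probe {probe!r}")
    fmax = X.max(skipna=True) if fmax is None else fmax
    y = outcome.loc[X.index].astype(int)
    ev = X.index[y == 1]
    no = X.index[y == 0]

    # vectorized |x_a - x_b| / fmax averaged over important features
    fm = fmax[important].to_numpy(dtype=float)
    if np.any(fm <= 0):
        raise ValueError("non-positive feature maxima")
    A = X.loc[ev, important].to_numpy(dtype=float) / fm
    Bm = X.loc[no, important].to_numpy(dtype=float) / fm
    D = np.abs(A[:, None, :] - Bm[None, :, :]).mean(axis=2)  # NaN propagates

    ii, jj = np.nonzero(np.nan_to_num(D, nan=np.inf) < threshold)
    candidates = sorted(
        zip(D[ii, jj], ev[ii], no[jj]), key=lambda t: (t[0], str(t[1]), str(t[2]))
    )
    used: set = set()
    pairs = []
    for d, pa, pb in candidates:
        if pa in used or pb in used:
            continue
        used.update((pa, pb))
        pairs.append((pa, pb, float(d)))
    if not pairs:
        logger.warning("no eligible pairs for probe %r at threshold %g", probe, threshold)
    return PairedSet(probe=probe, important=important, threshold=threshold, pairs=pairs)


@dataclass
class PairedTestResult:
    t_statistic: float
    p_value: float
    n_pairs: int
    mean_event: float
    mean_no_event: float
    mean_difference: float
    degenerate: bool = False


def paired_test(paired: PairedSet, values: pd.Series) -> PairedTestResult:
    """Two-sided paired t-test of the probe feature across matched pairs.

    Differences are (value in the lymphopenia member) minus (value in the
    non-lymphopenia member); pairs missing a probe value are dropped. A
    zero-variance difference vector is degenerate and flagged rather than
    tested.
    """
    rows = [
        (values.get(pa), values.get(pb))
        for pa, pb, _ in paired.pairs
        if pd.notna(values.get(pa)) and pd.notna(values.get(pb))
    ]
    if len(rows) < 2:
        raise ValueError("need >= 2 pairs with non-missing probe values")
    a = np.array([r[0] for r in rows], dtype=float)
    b = np.array([r[1] for r in rows], dtype=float)
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        return PairedTestResult(
            t_statistic=np.nan, p_value=np.nan, n_pairs=len(rows),
            mean_event=float(a.mean()), mean_no_event=float(b.mean()),
            mean_difference=float(diff.mean()), degenerate=True,
        )
    t, p = ttest_rel(a, b)
    return PairedTestResult(
        t_statistic=float(t), p_value=float(p), n_pairs=len(rows),
        mean_event=float(a.mean()), mean_no_event=float(b.mean()),
        mean_difference=float(diff.mean()),
    )
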