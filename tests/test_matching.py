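import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radlymph.matching import (
    PairedSet,
    discrepancy,
    important_features,
    paired_test,
    select_pairs,
)


def _series(vals, names):
    return pd.Series(dict(zip(names, vals)))


class TestDiscrepancy:
    NAMES = list("abcde")
    FMAX = pd.Series(1.0, index=list("abcde"))

    def test_identical_patients(self):
        a = _series([1, 2, 3, 4, 5.0], self.NAMES)
        assert discrepancy(a, a.copy(), self.NAMES, self.FMAX * 10) == 0.0

    def test_unit_numerator(self):
        # differ on one of n=5 features by exactly that feature's maximum
        a = _series([0.0, 0, 0, 0, 0], self.NAMES)
        b = _series([7.0, 0, 0, 0, 0], self.NAMES)
        fmax = pd.Series([7.0, 1, 1, 1, 1], index=self.NAMES)
        assert discrepancy(a, b, self.NAMES, fmax) == pytest.approx(1 / 5)

    @given(st.lists(st.floats(-50, 50), min_size=10, max_size=10))
    @settings(max_examples=50, deadline=None)
    def test_matches_independent_arithmetic_oracle(self, vals):
        a = _series(vals[:5], self.NAMES)
        b = _series(vals[5:], self.NAMES)
        fmax = pd.Series([60.0, 55.0, 70.0, 51.0, 90.0], index=self.NAMES)
        got = discrepancy(a, b, self.NAMES, fmax)
        # second, independently coded rendering of the printed formula
        expected = sum(
            abs(a[f] - b[f]) / fmax[f] for f in self.NAMES
        ) / len(self.NAMES)
        assert got == pytest.approx(expected, abs=1e-12)

    @given(st.lists(st.floats(-10, 10), min_size=10, max_size=10))
    @settings(max_examples=25, deadline=None)
    def test_symmetric(self, vals):
        a = _series(vals[:5], self.NAMES)
        b = _series(vals[5:], self.NAMES)
        assert discrepancy(a, b, self.NAMES, self.FMAX) == discrepancy(
            b, a, self.NAMES, self.FMAX
        )

    def test_missing_value_makes_pair_ineligible(self):
        a = _series([np.nan, 1, 1, 1, 1], self.NAMES)
        b = _series([1.0, 1, 1, 1, 1], self.NAMES)
        assert np.isnan(discrepancy(a, b, self.NAMES, self.FMAX))

    def test_nonpositive_maximum_rejected(self):
        a = _series([1.0] * 5, self.NAMES)
        with pytest.raises(ValueError):
            discrepancy(a, a, self.NAMES, self.FMAX * 0)


def _toy_cohort(n=60, seed=0, probe_shift=0.0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        {
            "big1": rng.normal(size=n),
            "big2": rng.normal(size=n),
            "probe": rng.normal(size=n),
        },
        index=[f"p{i:03d}" for i in range(n)],
    )
    y = pd.Series(np.tile([0, 1], n // 2), index=X.index)
    X["probe"] += probe_shift * y
    X -= X.min() - 0.1  # keep positive so fmax > 0
    summary = pd.Series({"big1": 3.0, "big2": 2.0, "probe": 0.5})
    return X, y, summary


class TestSelectPairs:
    def test_probe_excluded_from_own_importance_set(self):
        _, _, summary = _toy_cohort()
        assert "probe" not in important_features(summary, "probe")
        assert important_features(summary, "probe") == ["big1", "big2"]

    def test_all_selected_pairs_below_threshold_and_discordant(self):
        X, y, summary = _toy_cohort(seed=3)
        ps = select_pairs(X, y, "probe", summary, threshold=0.15)
        assert len(ps) > 0
        for pa, pb, d in ps.pairs:
            assert d < 0.15
            assert y[pa] == 1 and y[pb] == 0

    def test_no_patient_reused(self):
        X, y, summary = _toy_cohort(seed=4)
        ps = select_pairs(X, y, "probe", summary, threshold=0.3)
        ids = [p for pair in ps.pairs for p in pair[:2]]
        assert len(ids) == len(set(ids))

    def test_threshold_monotonicity(self):
        X, y, summary = _toy_cohort(seed=5)
        counts = [
            len(select_pairs(X, y, "probe", summary, threshold=t))
            for t in (0.05, 0.1, 0.2, 0.4)
        ]
        assert counts == sorted(counts)

    def test_tiny_threshold_empty_without_duplicates(self):
        X, y, summary = _toy_cohort(seed=6)
        ps = select_pairs(X, y, "probe", summary, threshold=1e-9)
        assert len(ps) == 0

    def test_deterministic(self):
        X, y, summary = _toy_cohort(seed=7)
        a = select_pairs(X, y, "probe", summary, threshold=0.2)
        b = select_pairs(X, y, "probe", summary, threshold=0.2)
        assert a.pairs == b.pairs

    def test_pairedset_enforces_threshold(self):
        with pytest.raises(ValueError):
            PairedSet(probe="p", important=["a"], threshold=0.1,
                      pairs=[("x", "y", 0.2)])


class TestPairedTest:
    def _paired_set(self, n):
        pairs = [(f"e{i}", f"c{i}", 0.0) for i in range(n)]
        return PairedSet(probe="probe", important=["big"], threshold=1.0, pairs=pairs)

    def _values(self, a, b):
        vals = {}
        for i, (x, y) in enumerate(zip(a, b)):
            vals[f"e{i}"], vals[f"c{i}"] = x, y
        return pd.Series(vals)

    def test_hand_computed_five_pair_example(self):
        a = np.array([3.1, 2.9, 3.5, 3.0, 3.3])
        b = np.array([2.8, 2.5, 3.1, 3.2, 2.9])
        res = paired_test(self._paired_set(5), self._values(a, b))
        d = a - b
        t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        assert res.t_statistic == pytest.approx(t_expected, abs=1e-10)

    def test_zero_variance_degenerate(self):
        a = np.ones(4)
        res = paired_test(self._paired_set(4), self._values(a, a * 0))
        assert res.degenerate and np.isnan(res.p_value)

    def test_type_i_error_under_null(self):
        # 10,000 replicates of 30 N(0,1) paired differences at alpha 0.05
        rng = np.random.default_rng(0)
        ps = self._paired_set(30)
        rejections = 0
        reps = 10_000
        diffs = rng.normal(size=(reps, 30))
        base = rng.normal(size=(reps, 30))
        for r in range(reps):
            res = paired_test(ps, self._values(base[r] + diffs[r], base[r]))
            rejections += res.p_value < 0.05
        assert 0.04 <= rejections / reps <= 0.06

    def test_planted_effect_detected_after_matching(self):
        # matched pairs where the probe truly differs by outcome: the
        # paired t-test flags it in >= 80% of replicates at 50 pairs
        hits = 0
        reps = 20
        for r in range(reps):
            X, y, summary = _toy_cohort(n=160, seed=100 + r, probe_shift=0.8)
            ps = select_pairs(X, y, "probe", summary, threshold=0.25)
            if len(ps) < 2:
                continue
            res = paired_test(ps, X["probe"])
            hits += res.p_value < 0.05
        assert hits >= 0.8 * reps
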