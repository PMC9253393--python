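import networkx as nx
import numpy as np
import pandas as pd
import pytest
import xgboost as xgb

from oracle_shapley import brute_force_shapley
from radlymph.attribution import (
    AttributionMatrix,
    direction_score,
    export_attribution_graph,
    per_instance_attributions,
    summarize_importance,
    summarize_attributions,
)


def _mat(values: np.ndarray, columns, base=None):
    df = pd.DataFrame(values, columns=columns)
    return AttributionMatrix(df, base if base is not None else np.zeros(len(df)))


class TestTreePathAttributions:
    def test_depth2_tree_matches_brute_force_shapley(self):
        # all 8 corners of a 3-binary-feature cube through a depth-2 tree
        rng = np.random.default_rng(0)
        grid = np.array([[a, b, c] for a in (0, 1) for b in (0, 1) for c in (0, 1)])
        X = np.repeat(grid, 4, axis=0).astype(float)
        y = 3.0 * X[:, 0] + 2.0 * X[:, 1] * X[:, 0] + rng.normal(0, 0.01, len(X))
        model = xgb.XGBRegressor(
            n_estimators=1, max_depth=2, learning_rate=1.0, reg_lambda=0.0,
            min_child_weight=0, base_score=0.0, tree_method="exact",
        )
        model.fit(X, y)
        booster = model.get_booster()
        contribs = booster.predict(xgb.DMatrix(grid.astype(float)), pred_contribs=True)
        for row, x in enumerate(grid.astype(float)):
            phi = brute_force_shapley(booster, x, ["f0", "f1", "f2"])
            np.testing.assert_allclose(contribs[row, :-1], phi, atol=1e-6)

    def test_multi_tree_model_matches_brute_force_shapley(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 3))
        y = (X[:, 0] + 0.5 * X[:, 1] * X[:, 0] > 0).astype(int)
        model = xgb.XGBClassifier(n_estimators=5, max_depth=3, learning_rate=0.3)
        model.fit(X, y)
        booster = model.get_booster()
        pts = X[:5]
        contribs = booster.predict(xgb.DMatrix(pts), pred_contribs=True)
        for row, x in enumerate(pts):
            phi = brute_force_shapley(booster, x, ["f0", "f1", "f2"])
            np.testing.assert_allclose(contribs[row, :-1], phi, atol=1e-5)

    def test_single_stump_attributes_one_feature_only(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"a": rng.normal(size=100), "b": rng.normal(size=100)})
        y = (X["a"] > 0).astype(int)
        model = xgb.XGBClassifier(n_estimators=1, max_depth=1)
        model.fit(X, y)
        mat = per_instance_attributions(model, X)
        assert (mat.values["b"] == 0).all()
        assert (mat.values["a"] != 0).any()

    def test_local_accuracy_identity(self, small_matrix, fitted_iterations):
        it = fitted_iterations[0]
        Xte = small_matrix.X.iloc[it.plan.test]
        mat = per_instance_attributions(it.model, Xte, check_local_accuracy=False)
        margin = it.model.get_booster().predict(
            xgb.DMatrix(Xte, missing=np.nan), output_margin=True
        )
        assert np.max(np.abs(mat.raw_predictions() - margin)) < 1e-4

    def test_column_mismatch_rejected_by_name(self, small_matrix, fitted_iterations):
        it = fitted_iterations[0]
        bad = small_matrix.X.rename(columns={"age": "years"})
        with pytest.raises(ValueError, match="years"):
            per_instance_attributions(it.model, bad)


class TestImportance:
    def test_all_zeros(self):
        imp = summarize_importance([_mat(np.zeros((4, 2)), ["a", "b"])])
        assert (imp == 0).all()

    def test_abs_before_mean(self):
        imp = summarize_importance([_mat(np.array([[-2.0], [2.0]]), ["a"])])
        assert imp["a"] == 2.0

    def test_mean_over_iterations(self):
        m1 = _mat(np.array([[1.0], [1.0]]), ["a"])
        m2 = _mat(np.array([[3.0], [3.0]]), ["a"])
        assert summarize_importance([m1, m2])["a"] == 2.0

    def test_single_strong_plant_ranks_first(self):
        # a lone strong effect dominates mean |SHAP| in >= 90% of replicates
        from radlymph import modeling, synthetic
        from radlymph.preprocess import encode

        hits, reps = 0, 5
        for r in range(reps):
            cfg = synthetic.default_config(
                n_patients=250, seed=700 + r, missingness_rate=0.0,
                effect_vector={"baseline_lymphocytes": 2.0},
            )
            cohort, _, _ = synthetic.generate_cohort(cfg)
            matrix = encode(cohort, synthetic.default_schema())
            its = modeling.run_bootstrap(matrix, B=2, seed=r, mode="fast",
                                         fit_lasso=False, n_estimators=100)
            mats = [
                per_instance_attributions(it.model, matrix.X.iloc[it.plan.test])
                for it in its
            ]
            hits += summarize_importance(mats).idxmax() == "baseline_lymphocytes"
        assert hits >= 0.9 * reps


class TestDirection:
    def test_attributions_identical_to_outcomes(self):
        y = np.array([0.0, 1, 0, 1, 1, 0])
        mat = _mat(y[:, None], ["a"])
        assert direction_score([mat], [y])["a"] == pytest.approx(1.0)

    def test_attributions_opposite_to_outcomes(self):
        y = np.array([0.0, 1, 0, 1, 1, 0])
        mat = _mat(-y[:, None], ["a"])
        assert direction_score([mat], [y])["a"] == pytest.approx(-1.0)

    def test_constant_attribution_contributes_zero(self):
        y = np.array([0.0, 1, 0, 1])
        mat = _mat(np.ones((4, 1)), ["a"])
        assert direction_score([mat], [y])["a"] == 0.0

    def test_outcome_relabeling_flips_sign(self):
        rng = np.random.default_rng(2)
        y = np.tile([0.0, 1.0], 20)
        vals = rng.normal(size=(40, 3)) + y[:, None]
        mat = _mat(vals, ["a", "b", "c"])
        d = direction_score([mat], [y])
        d_flip = direction_score([mat], [1 - y])
        np.testing.assert_allclose(d.to_numpy(), -d_flip.to_numpy(), atol=1e-12)

    def test_protective_plant_strongly_negative_in_feature_mode(self, attribution_bundle):
        mats, outcomes, feats = attribution_bundle
        d = direction_score(mats, outcomes, against="feature", feature_values=feats)
        assert d["baseline_lymphocytes"] < -0.5
        assert d["integral_body_dose"] > 0.5

    def test_misaligned_lengths_rejected(self):
        mat = _mat(np.zeros((4, 1)), ["a"])
        with pytest.raises(ValueError):
            direction_score([mat], [np.zeros(5)])


class TestGraphExport:
    def _summary(self):
        return pd.DataFrame(
            {"mean_abs_shap": [2.0, 1.0, 0.0], "direction": [0.9, -0.4, 0.0]},
            index=["dose", "lym", "unused"],
        )

    def test_node_and_edge_counts(self, tmp_path):
        g = export_attribution_graph(self._summary(), path=tmp_path / "g.graphml")
        assert g.number_of_nodes() == 3  # 2 features + outcome; zero-importance excluded
        assert g.number_of_edges() == 2
        assert "unused" not in g

    def test_edge_signs_match_directions(self, tmp_path):
        path = tmp_path / "g.graphml"
        export_attribution_graph(self._summary(), path=path)
        g = nx.read_graphml(path)
        assert g.edges["dose", "lymphopenia"]["sign"] == 1
        assert g.edges["lym", "lymphopenia"]["sign"] == -1

    def test_summary_table_zero_importance_zero_direction(self, attribution_bundle):
        mats, outcomes, feats = attribution_bundle
        table = summarize_attributions(mats, outcomes, feature_values=feats)
        unused = table[table["mean_abs_shap"] == 0]
        assert (unused["direction"] == 0).all()
        assert table["direction"].between(-1, 1).all()
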