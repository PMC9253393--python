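import numpy as np
import pandas as pd
import pytest

from radlymph import modeling
from radlymph.modeling import (
    PAPER_HYPERPARAMETERS,
    HyperGrid,
    evaluate,
    fit_penalized,
    make_plans,
    metrics_frame,
    run_group_models,
    summarize_metrics,
    tune_tree_model,
)


class TestPlans:
    def test_draw_and_split_arithmetic(self):
        plans = make_plans(589, B=3, seed=0)
        for p in plans:
            assert len(p.draw) == 471  # floor(0.8 * 589)
            assert len(p.train) == 329  # floor(0.7 * 471)
            assert len(p.test) == 142
            assert len(np.intersect1d(p.train, p.test)) == 0
            assert set(np.unique(p.folds)) == set(range(10))

    def test_determinism(self):
        y = np.tile([0, 1], 50)
        a = make_plans(100, B=1, seed=5, outcome=y)[0]
        b = make_plans(100, B=1, seed=5, outcome=y)[0]
        assert np.array_equal(a.draw, b.draw)
        assert np.array_equal(a.train, b.train)
        assert np.array_equal(a.folds, b.folds)

    def test_stratification_preserves_prevalence(self):
        rng = np.random.default_rng(1)
        y = (rng.uniform(size=600) < 0.3).astype(int)
        p = make_plans(600, B=1, seed=2, outcome=y)[0]
        rate = y.mean()
        assert abs(y[p.train].mean() - rate) < 0.03
        assert abs(y[p.test].mean() - rate) < 0.05

    def test_invalid_b_rejected(self):
        with pytest.raises(ValueError):
            make_plans(100, B=0)


class TestHyperGrid:
    def test_stated_grid_cardinality(self):
        assert HyperGrid().cardinality == 552_960

    def test_paper_configuration_inside_grid(self):
        axes = HyperGrid().axes
        for key, value in PAPER_HYPERPARAMETERS.items():
            assert value in axes[key]

    def test_fast_mode_returns_published_configuration(self):
        X = pd.DataFrame({"a": np.arange(20.0)})
        y = np.tile([0, 1], 10)
        params = tune_tree_model(X, y, np.arange(20) % 5, mode="fast")
        assert params == PAPER_HYPERPARAMETERS

    def test_single_candidate_returned_without_search(self):
        one = HyperGrid(
            learning_rate=(0.04,), gamma=(5,), max_depth=(3,),
            scale_pos_weight=(1.8,), subsample=(0.8,), colsample_bytree=(0.7,),
            min_child_weight=(5,), max_delta_step=(1,),
        )
        X = pd.DataFrame({"a": np.arange(20.0)})
        params = tune_tree_model(X, np.tile([0, 1], 10), np.arange(20) % 5,
                                 grid=one, mode="full")
        assert params["learning_rate"] == 0.04 and params["gamma"] == 5

    def test_tuned_model_beats_null_on_planted_signal(self, small_matrix):
        view = small_matrix.select_columns(["baseline_lymphocytes", "integral_body_dose"])
        plan = make_plans(len(view.X), B=1, seed=3, outcome=view.y.to_numpy())[0]
        Xtr, ytr = view.X.iloc[plan.train], view.y.to_numpy()[plan.train]
        params = tune_tree_model(
            Xtr, ytr, plan.folds, mode="random", n_candidates=3, seed=0,
            n_estimators=50,
        )
        model = modeling._make_classifier(params, 0, 50)
        model.fit(Xtr, ytr)
        yte = view.y.to_numpy()[plan.test]
        auc = evaluate(yte, model.predict_proba(view.X.iloc[plan.test])[:, 1]).roc_auc
        assert auc >= 0.6  # intercept-only AUC is 0.5


class TestPenalized:
    def test_full_shrinkage_limit(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(80, 5)), columns=list("abcde"))
        y = (rng.uniform(size=80) < 0.5).astype(int)
        fit = fit_penalized(X, y, Cs=[1e-8], seed=0)
        assert (fit.coef == 0).all()

    def test_sign_recovery_of_strong_effect(self):
        rng = np.random.default_rng(3)
        hits = 0
        for it in range(20):
            X = pd.DataFrame(rng.normal(size=(300, 6)), columns=list("abcdef"))
            eta = 2.0 * X["a"]
            y = (rng.uniform(size=300) < 1 / (1 + np.exp(-eta))).astype(int)
            fit = fit_penalized(X, y, seed=it)
            hits += fit.coef["a"] > 0
        assert hits >= 19  # >= 95% of iterations

    def test_noise_features_rarely_selected(self):
        rng = np.random.default_rng(8)
        selected = np.zeros(8)
        for it in range(20):
            X = pd.DataFrame(rng.normal(size=(400, 8)),
                             columns=[f"n{i}" for i in range(8)])
            y = (rng.uniform(size=400) < 0.5).astype(int)
            fit = fit_penalized(X, y, seed=it)
            selected += fit.selected.to_numpy()
        assert (selected / 20 < 0.5).all()

    def test_constant_column_dropped(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"a": rng.normal(size=60), "const": np.ones(60)})
        y = (X["a"] > 0).astype(int).to_numpy()
        fit = fit_penalized(X, y, seed=0)
        assert fit.dropped_constant == ["const"]

    def test_requires_complete_cases(self):
        X = pd.DataFrame({"a": [1.0, np.nan] * 20})
        with pytest.raises(ValueError):
            fit_penalized(X, np.tile([0, 1], 20))


class TestEvaluate:
    def test_perfect_ranking(self):
        y = np.array([0, 0, 1, 1])
        ms = evaluate(y, np.array([0.1, 0.2, 0.8, 0.9]))
        assert ms.roc_auc == 1.0 and ms.pr_auc == 1.0

    def test_hand_built_confusion_case(self):
        # 8 samples, threshold 0.5: TP=2, FN=1, TN=3, FP=2
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0])
        s = np.array([0.9, 0.7, 0.2, 0.6, 0.8, 0.1, 0.3, 0.4])
        ms = evaluate(y, s)
        assert ms.sensitivity == pytest.approx(2 / 3)
        assert ms.specificity == pytest.approx(3 / 5)
        assert ms.accuracy == pytest.approx(5 / 8)
        assert ms.f1 == pytest.approx(2 * 2 / (2 * 2 + 2 + 1))
        # exhaustive trapezoid over the 15 empirical ROC points
        pos = s[y == 1][:, None]
        neg = s[y == 0][None, :]
        auc = (np.sum(pos > neg) + 0.5 * np.sum(pos == neg)) / (3 * 5)
        assert ms.roc_auc == pytest.approx(auc)

    def test_random_scores_near_half_auc(self):
        rng = np.random.default_rng(0)
        y = np.tile([0, 1], 5000)
        ms = evaluate(y, rng.uniform(size=10_000))
        assert ms.roc_auc == pytest.approx(0.5, abs=0.02)

    def test_single_class_aucs_missing(self):
        ms = evaluate(np.ones(5, dtype=int), np.linspace(0, 1, 5))
        assert np.isnan(ms.roc_auc) and np.isnan(ms.pr_auc)
        assert np.isfinite(ms.accuracy)


class TestEngine:
    def test_reproducible_metric_tables(self, small_matrix):
        a = modeling.run_bootstrap(small_matrix, B=2, seed=4, mode="fast", fit_lasso=False)
        b = modeling.run_bootstrap(small_matrix, B=2, seed=4, mode="fast", fit_lasso=False)
        pd.testing.assert_frame_equal(metrics_frame(a), metrics_frame(b))

    def test_importance_indices_normalized(self, fitted_iterations):
        for it in fitted_iterations:
            assert it.gain.sum() == pytest.approx(1.0)
            assert it.frequency.sum() == pytest.approx(1.0)
            assert (it.gain >= 0).all() and (it.frequency >= 0).all()

    def test_lasso_used_complete_cases_only(self, small_matrix, fitted_iterations):
        it = fitted_iterations[0]
        Xtr = small_matrix.X.iloc[it.plan.train]
        n_complete = int((~Xtr.isna().any(axis=1)).sum())
        assert n_complete < len(Xtr)  # tree model saw more rows than lasso

    def test_group_models_smoke_and_signal_location(self, small_matrix):
        per_iter = run_group_models(small_matrix, B=2, seed=6, mode="fast",
                                    n_estimators=60)
        summary = summarize_metrics(per_iter)
        # 6 scopes x 1 learner-cohort minimum; 12 distributions at 2 learners
        assert set(summary["scope"]) == {"full", "clinical", "tumor", "blood",
                                         "radiotherapy", "treatment"}
        med = summary[(summary["metric"] == "roc_auc") & (summary["cohort"] == "test")
                      & (summary["learner"] == "xgboost")].set_index("scope")["median"]
        # planted signal concentrates in blood + radiotherapy, not clinical
        assert med["blood"] >= med["clinical"] + 0.05
        assert med["full"] >= med[["clinical", "tumor", "treatment"]].max() - 0.02
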