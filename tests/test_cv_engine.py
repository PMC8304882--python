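import numpy as np
import pytest
from scipy.optimize import minimize
from sklearn.preprocessing import MinMaxScaler

from rulepost import (
    Cohort,
    ModelConfig,
    PerformanceProfile,
    filter_selected_predictors,
    fit_cutoff,
    fit_model,
    predict,
    run_repeated_cv,
)
from rulepost.cv_engine import FittedModel, l1_logistic_objective


def identity_scaler():
    return MinMaxScaler().fit([[0.0], [1.0]])


class TestFitCutoff:
    @pytest.mark.parametrize(
        "y, expected",
        [((1, 0, 0, 1, 0, 0, 0, 0, 0, 0), 0.2), ((0, 1, 0, 1), 0.5)],
    )
    def test_positive_proportion(self, y, expected):
        assert fit_cutoff(np.array(y)) == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_cutoff(np.ones(5))


class TestFitModel:
    def test_extreme_penalty_shrinks_all_slopes(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 4))
        y = rng.integers(0, 2, size=50)
        model = fit_model(X, y, C=1e-6)
        assert np.allclose(model.coef, 0.0)

    def test_separable_predictor_gets_positive_slope(self):
        X = np.linspace(0, 1, 30).reshape(-1, 1)
        y = (X.ravel() > 0.5).astype(int)
        model = fit_model(X, y, C=1.0)
        assert model.coef[0] > 0

    def test_objective_matches_direct_convex_minimization(self):
        """The fitted objective value agrees with an independent scipy
        L-BFGS-B minimization of the same L1-penalized cross-entropy
        (split w = w+ - w-) to within 1e-6."""
        rng = np.random.default_rng(42)
        X = rng.normal(size=(20, 3))
        y = (rng.random(20) < 0.5).astype(int)
        C = 0.15
        Xs = MinMaxScaler().fit_transform(X)
        m = X.shape[1]

        def objective(z):
            w = z[:m] - z[m : 2 * m]
            margins = np.where(y == 1, 1.0, -1.0) * (Xs @ w + z[2 * m])
            return z[: 2 * m].sum() + C * np.logaddexp(0.0, -margins).sum()

        oracle = minimize(
            objective,
            np.zeros(2 * m + 1),
            method="L-BFGS-B",
            bounds=[(0, None)] * (2 * m) + [(None, None)],
            options={"maxiter": 20000, "ftol": 1e-16, "gtol": 1e-14},
        )
        model = fit_model(X, y, C=C)
        ours = l1_logistic_objective(model.coef, model.intercept, Xs, y, C)
        assert ours == pytest.approx(oracle.fun, abs=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_model(np.zeros((5, 2)), np.ones(5))


class TestPredict:
    def test_boundary_probability_classified_positive(self):
        model = FittedModel(coef=np.zeros(1), intercept=0.0, scaler=identity_scaler())
        X = np.array([[0.3], [0.8]])
        assert predict(model, X, alpha=0.5).tolist() == [1, 1]  # P = 0.5 >= 0.5
        assert predict(model, X, alpha=0.51).tolist() == [0, 0]

    def test_hand_computed_sigmoid(self):
        # w=1, w0=-0.5: sigmoid(0.2-0.5)=0.426 < 0.5, sigmoid(0.9-0.5)=0.599 >= 0.5
        model = FittedModel(coef=np.array([1.0]), intercept=-0.5, scaler=identity_scaler())
        assert predict(model, np.array([[0.2], [0.9]]), alpha=0.5).tolist() == [0, 1]


class TestRunRepeatedCv:
    def test_single_run_partition_covers_everyone_once(self, random_cohort_factory):
        cohort = random_cohort_factory(n=40, m=4, seed=6)
        profile = run_repeated_cv(cohort, ModelConfig(n_runs=1, n_folds=2, base_seed=0))
        assert np.array_equal(profile.n_predictions, np.ones(40))

    def test_tallies_sum_to_n_runs_and_split_by_class(self, random_cohort_factory):
        cohort = random_cohort_factory(n=50, m=4, seed=7)
        profile = run_repeated_cv(cohort, ModelConfig(n_runs=3, n_folds=5, base_seed=1))
        assert np.array_equal(profile.n_predictions, np.full(50, 3))
        pos = profile.y == 1
        assert np.array_equal(profile.tp[pos] + profile.fn[pos], profile.n_predictions[pos])
        assert not profile.tn[pos].any() and not profile.fp[pos].any()

    def test_reproducible_under_base_seed(self, random_cohort_factory):
        cohort = random_cohort_factory(n=40, m=4, seed=8)
        config = ModelConfig(n_runs=2, n_folds=4, base_seed=11)
        a = run_repeated_cv(cohort, config)
        b = run_repeated_cv(cohort, config)
        for field in ("tp", "fn", "tn", "fp"):
            assert np.array_equal(getattr(a, field), getattr(b, field))
        assert a.selected_predictors == b.selected_predictors

    def test_perfectly_learnable_signal(self):
        # y equals a single binary predictor: accuracy should be near-perfect
        rng = np.random.default_rng(5)
        X = (rng.random((200, 5)) < 0.5).astype(float)
        y = X[:, 0].astype(np.int8)
        cohort = Cohort([str(i) for i in range(200)], X, y,
                        [f"p{j}" for j in range(5)], ["dichotomous"] * 5)
        profile = run_repeated_cv(cohort, ModelConfig(n_runs=5, n_folds=5, base_seed=0))
        assert profile.accuracy >= 0.95

    def test_stratification_infeasible_raises(self):
        X = np.zeros((10, 2))
        y = np.array([1] + [0] * 9)
        cohort = Cohort([str(i) for i in range(10)], X, y, ["a", "b"], ["dichotomous"] * 2)
        with pytest.raises(ValueError, match="stratified"):
            run_repeated_cv(cohort, ModelConfig(n_runs=1, n_folds=5))


class TestProfile:
    def test_csv_roundtrip(self, tmp_path, random_cohort_factory):
        cohort = random_cohort_factory(n=30, m=4, seed=9)
        profile = run_repeated_cv(cohort, ModelConfig(n_runs=2, n_folds=3, base_seed=2))
        profile.to_csv(tmp_path / "p.csv")
        back = PerformanceProfile.from_csv(tmp_path / "p.csv")
        for field in ("y", "tp", "fn", "tn", "fp", "n_predictions"):
            assert np.array_equal(getattr(back, field), getattr(profile, field))
        assert back.subject_ids == profile.subject_ids

    def test_inconsistent_tallies_rejected(self):
        with pytest.raises(ValueError, match="tp \\+ fn"):
            PerformanceProfile(
                subject_ids=["a"], y=np.array([1]),
                tp=np.array([3]), fn=np.array([1]),
                tn=np.array([0]), fp=np.array([0]),
                n_predictions=np.array([5]),
            )


class TestFilterSelectedPredictors:
    def test_subset_kept_in_order(self, random_cohort_factory):
        cohort = random_cohort_factory(n=30, m=6, seed=10)
        profile = run_repeated_cv(cohort, ModelConfig(n_runs=1, n_folds=2, base_seed=0))
        profile.selected_predictors = frozenset({2, 5})
        out = filter_selected_predictors(cohort, profile)
        assert out.predictor_names == [cohort.predictor_names[2], cohort.predictor_names[5]]

    def test_heavy_shrinkage_selects_strictly_fewer(self):
        rng = np.random.default_rng(12)
        X = (rng.random((80, 10)) < 0.5).astype(float)
        y = rng.integers(0, 2, size=80).astype(np.int8)
        cohort = Cohort([str(i) for i in range(80)], X, y,
                        [f"p{j}" for j in range(10)], ["dichotomous"] * 10)
        profile = run_repeated_cv(cohort, ModelConfig(shrinkage_c=0.01, n_runs=2, n_folds=4))
        assert len(profile.selected_predictors) < cohort.m

    def test_empty_selection_rejected(self, random_cohort_factory):
        cohort = random_cohort_factory(n=30, m=4, seed=13)
        profile = run_repeated_cv(cohort, ModelConfig(n_runs=1, n_folds=2))
        profile.selected_predictors = frozenset()
        with pytest.raises(ValueError, match="selected"):
            filter_selected_predictors(cohort, profile)
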