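import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from staplr.data import make_folds
from staplr.glm import (
    PenaltySpec,
    compute_lambda_path,
    cv_select_lambda,
    fit_cv_logistic,
    fit_penalized_logistic,
    fit_path,
    logistic,
    logistic_objective,
    soft_threshold,
)
from tests.conftest import random_instance


class TestLogistic:
    def test_known_values(self):
        assert logistic(0.0) == 0.5
        assert logistic(1.0) == pytest.approx(0.7310585786300049, abs=1e-12)
        assert logistic(40.0) > 1 - 1e-15
        assert np.isfinite(logistic(800.0))

    @given(st.floats(-50, 50))
    def test_symmetry(self, x):
        assert logistic(-x) == pytest.approx(1.0 - logistic(x), abs=1e-12)


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "z, gamma, nonneg, expected",
        [(3.0, 1.0, False, 2.0), (-0.5, 1.0, False, 0.0), (-3.0, 1.0, True, 0.0),
         (-3.0, 1.0, False, -2.0), (0.0, 0.0, False, 0.0)],
    )
    def test_examples(self, z, gamma, nonneg, expected):
        assert soft_threshold(z, gamma, nonneg) == expected

    @given(st.floats(-100, 100), st.floats(0, 100))
    def test_shrinks_toward_zero(self, z, gamma):
        out = soft_threshold(z, gamma)
        assert abs(out) <= abs(z)
        assert out * z >= 0


class TestLambdaPath:
    def test_defaults_and_log_equispacing(self):
        rng = np.random.default_rng(0)
        X, y = random_instance(rng, n=50, p=8)
        path = compute_lambda_path(X, y, PenaltySpec(alpha=1.0))
        assert path.n_lambda == 100 and path.epsilon == 0.01
        assert path.lambda_min == pytest.approx(0.01 * path.lambda_max)
        ratios = path.values[1:] / path.values[:-1]
        assert np.allclose(ratios, ratios[0])
        assert np.all(np.diff(path.values) < 0)

    def test_ridge_surrogate_is_finite(self):
        rng = np.random.default_rng(1)
        X, y = random_instance(rng, n=40, p=5)
        path = compute_lambda_path(X, y, PenaltySpec(alpha=0.0))
        assert np.isfinite(path.lambda_max) and path.lambda_max > 0

    def test_nonnegative_path_collapses_without_positive_score(self):
        # features anti-correlated with the outcome: no slope can ever enter
        rng = np.random.default_rng(2)
        y = (rng.random(60) < 0.5).astype(float)
        X = -(y[:, None] + 0.1 * rng.standard_normal((60, 3)))
        pen = PenaltySpec(alpha=1.0, nonnegative=True, standardize=False)
        path = compute_lambda_path(X, y, pen)
        assert path.n_lambda == 1
        m = fit_penalized_logistic(X, y, pen, float(path.values[0]))
        assert np.all(m.coefficients == 0.0)

    def test_constant_outcome_rejected(self):
        X = np.random.default_rng(0).standard_normal((20, 3))
        with pytest.raises(ValueError, match="constant outcome"):
            compute_lambda_path(X, np.ones(20), PenaltySpec(alpha=1.0))


class TestFit:
    def test_unpenalized_matches_maximum_likelihood(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        X, y = random_instance(rng, n=200, p=4)
        m = fit_penalized_logistic(X, y, PenaltySpec(alpha=0.0, standardize=False), 0.0)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert m.intercept == pytest.approx(ref.params[0], abs=1e-4)
        np.testing.assert_allclose(m.coefficients, ref.params[1:], atol=1e-4)

    def test_huge_ridge_penalty_shrinks_slopes_away(self):
        rng = np.random.default_rng(6)
        X, y = random_instance(rng, n=50, p=6)
        m = fit_penalized_logistic(X, y, PenaltySpec(alpha=0.0), 1e8)
        assert np.abs(m.coefficients).max() < 1e-4

    def test_nonnegative_constraint_zeroes_negative_coefficients(self):
        rng = np.random.default_rng(7)
        X, y = random_instance(rng, n=60, p=6)
        free = fit_penalized_logistic(X, y, PenaltySpec(alpha=1.0, standardize=False), 0.02)
        neg = np.flatnonzero(free.coefficients < -1e-6)
        assert neg.size > 0, "instance should have at least one negative free coefficient"
        con = fit_penalized_logistic(
            X, y, PenaltySpec(alpha=1.0, nonnegative=True, standardize=False), 0.02
        )
        assert np.all(con.coefficients >= 0.0)
        assert np.all(con.coefficients[neg] == 0.0)

    def test_warm_path_equals_cold_fits(self):
        rng = np.random.default_rng(8)
        X, y = random_instance(rng, n=50, p=7)
        for pen in [PenaltySpec(alpha=0.0), PenaltySpec(alpha=1.0),
                    PenaltySpec(alpha=0.5, nonnegative=True)]:
            path = compute_lambda_path(X, y, pen, n_lambda=12)
            b0s, coefs = fit_path(X, y, pen, path.values)
            for k in [0, 5, 11]:
                cold = fit_penalized_logistic(X, y, pen, float(path.values[k]))
                assert abs(b0s[k] - cold.intercept) < 1e-6
                np.testing.assert_allclose(coefs[k], cold.coefficients, atol=1e-6)

    def test_lasso_shrinkage_is_monotone_along_path(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            X, y = random_instance(rng)
            pen = PenaltySpec(alpha=1.0)
            path = compute_lambda_path(X, y, pen, n_lambda=30)
            _, coefs = fit_path(X, y, pen, path.values)
            norms = np.abs(coefs).sum(axis=1)
            assert np.all(np.diff(norms) >= -1e-8)

    def test_predict_proba_closed_forms(self):
        m = fit_penalized_logistic(
            np.random.default_rng(0).standard_normal((30, 2)),
            np.array([0, 1] * 15, dtype=float),
            PenaltySpec(alpha=0.0), 1e9, feature_names=["a", "b"],
        )
        m.intercept, m.coefficients = 0.0, np.zeros(2)
        np.testing.assert_allclose(m.predict_proba(np.ones((4, 2))), 0.5)
        m.intercept, m.coefficients = 1.0, np.array([2.0, -1.0])
        assert m.predict_proba(np.array([1.0, 1.0]))[0] == pytest.approx(0.8807970779778823, abs=1e-12)
        with pytest.raises(ValueError, match="feature columns"):
            m.predict_proba(np.ones((2, 5)))
        import pandas as pd
        with pytest.raises(KeyError, match="missing feature columns"):
            m.predict_proba(pd.DataFrame({"a": [1.0]}))

    def test_predictions_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(10)
        X, y = random_instance(rng, n=40, p=3)
        m = fit_penalized_logistic(X, y, PenaltySpec(alpha=0.0), 0.5)
        p = m.predict_proba(X)
        assert np.all((p > 0) & (p < 1))


class TestCvSelect:
    def test_selection_from_grid_and_determinism(self):
        rng = np.random.default_rng(11)
        X, y = random_instance(rng, n=60, p=6)
        pen = PenaltySpec(alpha=1.0)
        path = compute_lambda_path(X, y, pen, n_lambda=25)
        plan = make_folds(y.astype(int), 5, seed=4)
        lam1, curve1 = cv_select_lambda(X, y, pen, path, plan)
        lam2, curve2 = cv_select_lambda(X, y, pen, path, plan)
        assert lam1 == lam2 and lam1 in path.values
        np.testing.assert_array_equal(curve1, curve2)
        assert curve1.shape == (25,)

    def test_pure_noise_favors_heavy_shrinkage(self):
        """With y independent of X the selected λ should usually sit in the
        top (most penalized) decile of the path."""
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            X = rng.standard_normal((60, 10))
            y = (rng.random(60) < 0.5).astype(float)
            if y.min() == y.max():
                continue
            pen = PenaltySpec(alpha=1.0)
            path = compute_lambda_path(X, y, pen, n_lambda=50)
            plan = make_folds(y.astype(int), 5, seed=seed)
            lam, _ = cv_select_lambda(X, y, pen, path, plan)
            if np.searchsorted(-path.values, -lam) < 5:  # top decile (largest λ)
                hits += 1
        assert hits > n_seeds / 2

    def test_fit_cv_records_curve_and_path(self):
        rng = np.random.default_rng(13)
        X, y = random_instance(rng, n=50, p=5)
        m = fit_cv_logistic(X, y, PenaltySpec(alpha=1.0), n_lambda=20, n_folds=4, seed=2)
        assert m.cv_curve.shape == (20,) and m.lambda_path.shape == (20,)
        assert m.lambda_selected in m.lambda_path


def test_objective_helper_matches_manual_computation():
    rng = np.random.default_rng(14)
    X, y = random_instance(rng, n=25, p=3)
    beta = np.array([0.3, -0.2, 0.0])
    eta = 0.1 + X @ beta
    manual = np.mean(np.log1p(np.exp(eta)) - y * eta) + 0.2 * (0.5 * np.abs(beta).sum() + 0.25 * beta @ beta)
    assert logistic_objective(X, y, 0.1, beta, 0.2, 0.5) == pytest.approx(manual, abs=1e-10)
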