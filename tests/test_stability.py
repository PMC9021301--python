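import itertools

import numpy as np
import pandas as pd
import pytest

from wayfind.stability import (
    ZeroResponseError,
    cv_select_lambda,
    lambda_grid,
    lambda_max,
    lasso_fit,
    mape,
    run_stability,
    standardize,
)


def lasso_sign_oracle(X, y, lam):
    """Exhaustive quadratic-program oracle for the standardized lasso:
    enumerate all sign patterns, solve the equality-constrained system,
    keep KKT-feasible candidates, return the lowest-objective one."""
    n, p = X.shape
    best, best_obj = None, np.inf
    for signs in itertools.product((-1, 0, 1), repeat=p):
        s = np.array(signs, float)
        S = np.flatnonzero(s != 0)
        beta = np.zeros(p)
        if S.size:
            A = X[:, S].T @ X[:, S] / n
            b = X[:, S].T @ y / n - lam * s[S]
            try:
                bS = np.linalg.solve(A, b)
            except np.linalg.LinAlgError:
                continue
            if np.any(np.sign(bS) != s[S]):
                continue
            beta[S] = bS
        r = y - X @ beta
        grad = X.T @ r / n
        if np.any(np.abs(grad[s == 0]) > lam + 1e-8):
            continue
        obj = 0.5 * np.mean(r**2) + lam * np.abs(beta).sum()
        if obj < best_obj:
            best_obj, best = obj, beta
    return best


class TestLassoFit:
    def test_zero_penalty_equals_ols(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0]) + rng.normal(0, 0.1, 30)
        fit = lasso_fit(X, y, 0.0)
        Xs, _, _ = standardize(X)
        ols = np.linalg.lstsq(Xs, y - y.mean(), rcond=None)[0]
        assert np.allclose(fit.coefficients, ols, atol=1e-6)

    def test_lambda_max_gives_null_model(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 6))
        y = rng.normal(size=40)
        Xs, _, _ = standardize(X)
        lam = lambda_max(Xs, y)
        fit = lasso_fit(Xs, y - y.mean(), lam * 1.0001, standardize_inputs=False)
        assert np.all(fit.coefficients == 0.0)

    def test_single_predictor_soft_threshold_closed_form(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 1))
        y = 0.8 * X[:, 0] + rng.normal(0, 0.3, 50)
        Xs, _, _ = standardize(X)
        yc = y - y.mean()
        rho = float(Xs[:, 0] @ yc / 50)
        for lam in (0.0, 0.1, abs(rho) * 2):
            fit = lasso_fit(Xs, yc, lam, standardize_inputs=False)
            want = np.sign(rho) * max(abs(rho) - lam, 0.0)
            assert fit.coefficients[0] == pytest.approx(want, abs=1e-7)

    def test_matches_sign_pattern_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(5, 15))
            p = int(rng.integers(1, 4))
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            Xs, _, _ = standardize(X)
            yc = y - y.mean()
            lam = float(rng.uniform(0.02, 1.2) * max(lambda_max(Xs, yc), 1e-6))
            fit = lasso_fit(Xs, yc, lam, standardize_inputs=False)
            oracle = lasso_sign_oracle(Xs, yc, lam)
            assert np.allclose(fit.coefficients, oracle, atol=1e-5)

    def test_matches_sklearn(self):
        from sklearn.linear_model import Lasso

        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 10))
        y = X[:, 0] - 0.5 * X[:, 3] + rng.normal(0, 0.5, 60)
        Xs, _, _ = standardize(X)
        yc = y - y.mean()
        for lam in (0.01, 0.05, 0.2):
            fit = lasso_fit(Xs, yc, lam, standardize_inputs=False)
            sk = Lasso(alpha=lam, fit_intercept=False, tol=1e-12, max_iter=200000)
            sk.fit(Xs, yc)
            assert np.allclose(fit.coefficients, sk.coef_, atol=1e-6)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            lasso_fit(np.array([[np.nan], [1.0]]), np.array([0.0, 1.0]), 0.1)


class TestMape:
    def test_perfect_prediction_zero(self):
        assert mape([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_case_ten_percent(self):
        assert mape([100.0, 100.0], [90.0, 110.0]) == pytest.approx(10.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        y = rng.uniform(1, 5, 20)
        yhat = y + rng.normal(0, 0.2, 20)
        assert mape(y, yhat) == pytest.approx(mape(7.3 * y, 7.3 * yhat))

    def test_zero_true_value_names_row(self):
        with pytest.raises(ZeroResponseError, match=r"rows \[1\]"):
            mape([1.0, 0.0, 2.0], [1.0, 1.0, 2.0])


class TestCvSelectLambda:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 8))
        y = X[:, 2] + rng.normal(0, 0.5, 40)
        Xs, _, _ = standardize(X)
        assert cv_select_lambda(Xs, y, rng=11) == cv_select_lambda(Xs, y, rng=11)

    def test_pure_noise_selects_near_lambda_max(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(50, 10))
            y = rng.normal(size=50)
            Xs, _, _ = standardize(X)
            lam = cv_select_lambda(Xs, y, rng=seed)
            grid = lambda_grid(lambda_max(Xs, y))
            # "near the null model": upper quarter of the log grid
            hits += int(lam >= grid[len(grid) // 4])
        assert hits >= 8

    def test_strong_signal_retained(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 10))
        y = 2.0 * X[:, 4] + rng.normal(0, 0.2, 60)
        Xs, _, _ = standardize(X)
        lam = cv_select_lambda(Xs, y, rng=0)
        fit = lasso_fit(Xs, y - y.mean(), lam, standardize_inputs=False)
        assert fit.coefficients[4] != 0.0

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="n_folds"):
            cv_select_lambda(np.zeros((5, 2)), np.zeros(5), n_folds=10)


def toy_features(n=40, p=20, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, p)), columns=[f"f{i:02d}" for i in range(p)]
    )
    return X, rng


class TestRunStability:
    def test_single_iteration_bounds(self):
        X, rng = toy_features()
        y = X["f03"].to_numpy() + rng.normal(0, 0.5, len(X)) + 10
        res = run_stability(X, y, n_iterations=1, seed=0)
        assert res.per_iteration_mape.shape == (1,)
        assert set(np.unique(res.retention_counts)) <= {0, 1}

    def test_bit_reproducible(self):
        X, rng = toy_features(seed=1)
        y = X["f00"].to_numpy() * 0.5 + rng.normal(0, 0.5, len(X)) + 5
        a = run_stability(X, y, n_iterations=8, seed=42)
        b = run_stability(X, y, n_iterations=8, seed=42)
        assert np.array_equal(a.retention_counts, b.retention_counts)
        assert np.array_equal(a.per_iteration_mape, b.per_iteration_mape)

    def test_planted_feature_has_max_retention(self):
        # effect explaining about half the response variance, n = 64
        rng = np.random.default_rng(11)
        X = pd.DataFrame(
            rng.normal(size=(64, 20)), columns=[f"f{i:02d}" for i in range(20)]
        )
        signal = X["f07"].to_numpy()
        y = signal + rng.normal(0, 1.0, 64) + 8.0
        res = run_stability(X, y, n_iterations=60, seed=3)
        assert res.top_features(1) == ["f07"]

    def test_zero_variance_response_rejected(self):
        X, _ = toy_features()
        with pytest.raises(ValueError, match="zero variance"):
            run_stability(X, np.ones(len(X)), n_iterations=2, seed=0)

    def test_response_with_zeros_rejected(self):
        X, rng = toy_features()
        y = rng.normal(size=len(X))
        y[3] = 0.0
        with pytest.raises(ZeroResponseError):
            run_stability(X, y, n_iterations=2, seed=0)

    def test_with_replacement_bootstrap_runs(self):
        X, rng = toy_features(seed=2)
        y = X["f01"].to_numpy() + rng.normal(0, 0.3, len(X)) + 4
        res = run_stability(X, y, n_iterations=5, seed=1, with_replacement=True)
        assert res.n_iterations == 5

    def test_ranking_orders_by_count(self):
        X, rng = toy_features(seed=3)
        y = X["f02"].to_numpy() * 2 + rng.normal(0, 0.2, len(X)) + 6
        res = run_stability(X, y, n_iterations=20, seed=9)
        rk = res.ranking()
        assert rk["retention_count"].is_monotonic_decreasing
        assert rk.loc[0, "feature"] == "f02"
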