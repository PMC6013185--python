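"""Elastic-net logistic regression: solver correctness and contracts."""

import numpy as np
import pytest

from omicscreen import (
    EnetConfig,
    cv_select_lambda,
    fit_path,
    kkt_violation,
    labels_to_binary,
    lambda_path,
    penalized_objective,
    soft_threshold,
)


def _logistic_data(rng, n=30, p=8, sparsity=3, scale=1.0):
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    beta[:sparsity] = scale * rng.standard_normal(sparsity)
    prob = 1 / (1 + np.exp(-(X @ beta)))
    y = (rng.random(n) < prob).astype(float)
    if y.min() == y.max():  # force both classes
        y[0] = 1 - y[0]
    return X, y


def _standardize(X):
    return (X - X.mean(0)) / X.std(0)


def prox_grad_oracle(X, y, lam, alpha, iters=200_000, tol=1e-13):
    """Independent FISTA minimizer of the penalized logistic objective.

    Smooth part: mean negative log-likelihood + ridge term; the l1 part is
    handled by its proximal map (soft-thresholding).  Intercept unpenalized.
    """
    n, p = X.shape
    A = np.column_stack([np.ones(n), X])
    L = np.linalg.norm(A, 2) ** 2 / (4 * n) + lam * (1 - alpha)
    step = 1.0 / L
    th = np.zeros(p + 1)
    z = th.copy()
    t = 1.0
    for _ in range(iters):
        eta = A @ z
        prob = 1 / (1 + np.exp(-eta))
        grad = A.T @ (prob - y) / n
        grad[1:] += lam * (1 - alpha) * z[1:]
        new = z - step * grad
        new[1:] = np.sign(new[1:]) * np.maximum(
            np.abs(new[1:]) - step * lam * alpha, 0.0
        )
        t_new = (1 + np.sqrt(1 + 4 * t**2)) / 2
        z = new + ((t - 1) / t_new) * (new - th)
        if np.max(np.abs(new - th)) < tol:
            th = new
            break
        th, t = new, t_new
    return th[0], th[1:]


class TestPrimitives:
    @pytest.mark.parametrize(
        "z,g,expected", [(3, 1, 2), (-0.5, 1, 0), (-3, 1, -2), (1.7, 0, 1.7)]
    )
    def test_soft_threshold(self, z, g, expected):
        assert soft_threshold(z, g) == pytest.approx(expected)

    def test_soft_threshold_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(1.0, -0.5)

    def test_null_objective_is_log2_on_balanced_labels(self, rng):
        X = rng.standard_normal((20, 5))
        y = np.repeat([0.0, 1.0], 10)
        obj = penalized_objective(0.0, np.zeros(5), X, y, 0.7, 0.5)
        assert obj == pytest.approx(np.log(2))

    def test_zero_lambda_equals_plain_nll(self, rng):
        X, y = _logistic_data(rng)
        beta = rng.standard_normal(8) * 0.1
        eta = 0.3 + X @ beta
        nll = -np.mean(y * eta - np.logaddexp(0, eta))
        assert penalized_objective(0.3, beta, X, y, 0.0, 0.5) == pytest.approx(nll)

    def test_l1_penalty_arithmetic(self, rng):
        X, y = _logistic_data(rng)
        beta = np.zeros(8)
        beta[2] = 2.0
        with_pen = penalized_objective(0.0, beta, X, y, 0.1, 1.0)
        without = penalized_objective(0.0, beta, X, y, 0.0, 1.0)
        assert with_pen - without == pytest.approx(0.2)


class TestLambdaPath:
    def test_all_zero_at_lambda_max_for_lasso(self, rng):
        """KKT at the null model: the path's largest lambda kills every
        coefficient, and the intercept is logit(ybar)."""
        X, y = _logistic_data(rng, n=40, p=12)
        cfg = EnetConfig(alpha=1.0, n_lambda=5)
        fit = fit_path(X, y, cfg)
        assert np.all(fit.coef_path[0] == 0.0)
        ybar = y.mean()
        assert fit.intercept_path[0] == pytest.approx(
            np.log(ybar / (1 - ybar)), abs=1e-6
        )

    def test_single_point_path(self, rng):
        X, y = _logistic_data(rng)
        lams = lambda_path(X, y, 1.0, n_lambda=1)
        assert lams.shape == (1,)

    def test_halving_ratio_extends_path_downward(self, rng):
        X, y = _logistic_data(rng)
        a = lambda_path(X, y, 0.5, n_lambda=10, lambda_min_ratio=0.1)
        b = lambda_path(X, y, 0.5, n_lambda=10, lambda_min_ratio=0.05)
        assert a[0] == pytest.approx(b[0])
        assert b[-1] < a[-1]

    def test_constant_labels_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(ValueError):
            lambda_path(X, np.ones(10), 0.5)

    def test_path_strictly_decreasing(self, rng):
        X, y = _logistic_data(rng)
        lams = lambda_path(X, y, 0.5)
        assert (np.diff(lams) < 0).all()


class TestSolver:
    def test_ridge_has_no_exact_zeros(self, rng):
        X, y = _logistic_data(rng, n=20, p=30)
        fit = fit_path(X, y, EnetConfig(alpha=0.0, n_lambda=20))
        assert np.all(fit.coef_path[-1] != 0.0)

    def test_lasso_selects_at_most_n(self, rng):
        X, y = _logistic_data(rng, n=10, p=205, sparsity=5, scale=2.0)
        fit = fit_path(X, y, EnetConfig(alpha=1.0))
        assert (np.count_nonzero(fit.coef_path, axis=1) <= 10).all()

    def test_matches_unpenalized_mle_at_tiny_lambda(self, rng):
        """lambda -> 0 on a well-posed n=40, p=5 problem recovers the
        Newton-Raphson logistic MLE (statsmodels oracle) within 1e-3."""
        import statsmodels.api as sm

        X, y = _logistic_data(rng, n=40, p=5, sparsity=2, scale=0.8)
        lams = np.geomspace(1.0, 1e-7, 40)
        fit = fit_path(X, y, EnetConfig(alpha=0.5, tol=1e-10), lambdas=lams)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(fit.intercept_path[-1], ref.params[0], atol=1e-3)
        np.testing.assert_allclose(fit.coef_path[-1], ref.params[1:], atol=1e-3)

    @pytest.mark.parametrize("alpha", [0.25, 0.5, 1.0])
    def test_agrees_with_proximal_gradient_oracle(self, alpha):
        """Coefficients match an independent FISTA minimizer of the same
        objective within 1e-4 on random small instances."""
        for seed in range(7):
            rng = np.random.default_rng(seed)
            X, y = _logistic_data(rng, n=30, p=8)
            Xs = _standardize(X)
            lam = 0.05
            lams = np.geomspace(0.5, lam, 15)
            fit = fit_path(
                Xs, y, EnetConfig(alpha=alpha, standardize=False, tol=1e-12),
                lambdas=lams,
            )
            b0_ref, b_ref = prox_grad_oracle(Xs, y, lam, alpha)
            np.testing.assert_allclose(fit.intercept_path[-1], b0_ref, atol=1e-4)
            np.testing.assert_allclose(fit.coef_path[-1], b_ref, atol=1e-4)

    def test_kkt_conditions_at_convergence(self):
        """Stationarity/subgradient conditions hold at every path point."""
        rng = np.random.default_rng(3)
        X, y = _logistic_data(rng, n=40, p=20)
        Xs = _standardize(X)
        cfg = EnetConfig(alpha=0.6, standardize=False, n_lambda=30, tol=1e-12)
        fit = fit_path(Xs, y, cfg)
        for k in range(fit.lambda_path.size):
            viol = kkt_violation(
                Xs, y, fit.intercept_path[k], fit.coef_path[k],
                fit.lambda_path[k], 0.6,
            )
            assert viol < 1e-5

    def test_objective_nonincreasing_across_cycles(self, rng):
        """The recorded penalized objective never increases across the
        solver's outer cycles at any path point."""
        X, y = _logistic_data(rng, n=30, p=50)
        fit = fit_path(X, y, EnetConfig(alpha=0.5))
        for row in fit.objective_trace:
            vals = row[~np.isnan(row)]
            assert (np.diff(vals) <= 1e-9).all()

    def test_support_grows_down_the_path(self, rng):
        X, y = _logistic_data(rng, n=30, p=40, sparsity=4, scale=1.5)
        fit = fit_path(X, y, EnetConfig(alpha=1.0))
        nnz = np.count_nonzero(fit.coef_path, axis=1)
        assert nnz[0] == 0
        assert nnz[-1] >= nnz[0]


class TestCrossValidation:
    def test_deterministic_under_fixed_seed(self, rng):
        X, y = _logistic_data(rng, n=30, p=20)
        cfg = EnetConfig(alpha=0.5, seed=17)
        a = cv_select_lambda(X, y, cfg)
        b = cv_select_lambda(X, y, cfg)
        assert a.lambda_chosen == b.lambda_chosen
        np.testing.assert_array_equal(a.cv_mean, b.cv_mean)
        np.testing.assert_array_equal(a.coef, b.coef)

    def test_one_se_rule_chooses_larger_lambda(self, rng):
        X, y = _logistic_data(rng, n=60, p=20, scale=1.5)
        f_min = cv_select_lambda(X, y, EnetConfig(alpha=0.5, lambda_rule="min"))
        f_1se = cv_select_lambda(X, y, EnetConfig(alpha=0.5, lambda_rule="one_se"))
        assert f_1se.lambda_chosen >= f_min.lambda_chosen

    def test_pure_noise_selects_little(self):
        """On pure noise at n=20, p=205 the one-SE elastic net usually
        selects nothing (consistent with near-nominal Type I error)."""
        from omicscreen import ScenarioSpec, simulate_dataset

        spec = ScenarioSpec(rho=0.0, n_total=20, deltas=(0.0, 0.0, 0.0))
        empty = 0
        for r in range(10):
            ds = simulate_dataset(spec, np.random.default_rng(300 + r))
            fit = cv_select_lambda(
                ds.values, labels_to_binary(ds.labels),
                EnetConfig(alpha=0.5, seed=r),
            )
            empty += fit.selected.sum() == 0
        assert empty >= 7

    def test_ridge_selects_everything(self, small_dataset):
        fit = cv_select_lambda(
            small_dataset.values, labels_to_binary(small_dataset.labels),
            EnetConfig(alpha=0.0, seed=5),
        )
        assert fit.selected.all()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            EnetConfig(alpha=1.5)
        with pytest.raises(ValueError):
            EnetConfig(cv_folds=1)
        with pytest.raises(ValueError):
            EnetConfig(lambda_rule="best")
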