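"""Elastic-net penalized logistic regression with a cross-validated lambda path.

The model treats the feature vector of each sample as predictors of a
binary group label and maximizes the penalized log-likelihood

    (1/n) sum_j [ y_j eta_j - log(1 + exp(eta_j)) ]
        - lambda [ (1-alpha)/2 ||beta||_2^2 + alpha ||beta||_1 ],

where ``alpha`` splits the penalty between ridge (alpha = 0) and LASSO
(alpha = 1).  Selection is by non-zero coefficients at a lambda chosen by
k-fold cross-validation (binomial deviance; one-standard-error rule by
default).  The path solver (coordinate descent inside IRLS, warm starts,
soft-thresholding) lives in :mod:`omicscreen._solver`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from ._solver import enet_logistic_path

__all__ = [
    "EnetConfig",
    "EnetFit",
    "penalized_objective",
    "soft_threshold",
    "lambda_path",
    "fit_path",
    "cv_select_lambda",
    "selected_set",
    "kkt_violation",
    "labels_to_binary",
]

_ALPHA_FLOOR = 1e-3  # keeps lambda_max finite on the ridge path
_MAX_IRLS = 30


@dataclass(frozen=True)
class EnetConfig:
    """Solver and cross-validation settings.

    ``lambda_min_ratio`` defaults to 0.01 when n < p and 1e-4 otherwise
    (the standard pathwise convention).  ``lambda_rule`` is ``"one_se"``
    (largest lambda within one standard error of the CV minimum) or
    ``"min"``.
    """

    alpha: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float | None = None
    cv_folds: int = 10
    lambda_rule: str = "one_se"
    cv_loss: str = "deviance"
    max_sweeps: int = 100_000
    tol: float = 1e-7
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.lambda_rule not in ("min", "one_se"):
            raise ValueError("lambda_rule must be 'min' or 'one_se'")
        if self.cv_loss not in ("deviance", "misclassification"):
            raise ValueError("cv_loss must be 'deviance' or 'misclassification'")


@dataclass
class EnetFit:
    """A fitted lambda path, optionally with CV curve and chosen lambda.

    Coefficients are on the original data scale.  ``selected`` marks the
    features with exactly non-zero coefficients at ``lambda_chosen`` — the
    soft-threshold update produces exact zeros for alpha > 0, so no epsilon
    cutoff is applied.
    """

    alpha: float
    lambda_path: np.ndarray
    coef_path: np.ndarray  # (n_lambda, p)
    intercept_path: np.ndarray
    converged: np.ndarray
    objective_trace: np.ndarray
    cv_mean: np.ndarray | None = None
    cv_se: np.ndarray | None = None
    lambda_chosen: float | None = None
    lambda_chosen_index: int | None = None

    @property
    def coef(self) -> np.ndarray:
        if self.lambda_chosen_index is None:
            raise ValueError("no lambda chosen; run cv_select_lambda")
        return self.coef_path[self.lambda_chosen_index]

    @property
    def intercept(self) -> float:
        if self.lambda_chosen_index is None:
            raise ValueError("no lambda chosen; run cv_select_lambda")
        return float(self.intercept_path[self.lambda_chosen_index])

    @property
    def selected(self) -> np.ndarray:
        return self.coef != 0.0


def labels_to_binary(labels: np.ndarray) -> np.ndarray:
    """Map a two-group label vector to {0, 1} (higher group label -> 1)."""
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.shape[0] != 2:
        raise ValueError(f"expected exactly two classes, got {groups.tolist()}")
    return (labels == groups[1]).astype(np.float64)


def soft_threshold(z: float, gamma: float) -> float:
    """``sign(z) * max(|z| - gamma, 0)`` — the lasso coordinate update."""
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    return float(np.sign(z) * max(abs(z) - gamma, 0.0))


def penalized_objective(
    beta0: float,
    beta: np.ndarray,
    X: np.ndarray,
    y01: np.ndarray,
    lam: float,
    alpha: float,
) -> float:
    """Minimization form of the penalized likelihood (negative mean
    log-likelihood plus elastic-net penalty).  Reference implementation used
    by tests and diagnostics, not by the solver's hot loop."""
    y = np.asarray(y01, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y01 must be coded 0/1")
    beta = np.asarray(beta, dtype=float)
    eta = beta0 + X @ beta
    nll = -np.mean(y * eta - np.logaddexp(0.0, eta))
    penalty = lam * ((1.0 - alpha) / 2.0 * np.sum(beta**2) + alpha * np.sum(np.abs(beta)))
    return float(nll + penalty)


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    center = X.mean(axis=0)
    scale = X.std(axis=0)  # population SD, matching the reference convention
    scale = np.where(scale > 0, scale, 1.0)
    return (X - center) / scale, center, scale


def lambda_path(
    X: np.ndarray,
    y01: np.ndarray,
    alpha: float,
    n_lambda: int = 100,
    lambda_min_ratio: float | None = None,
    standardize: bool = True,
) -> np.ndarray:
    """Geometric decreasing lambda sequence from the null-model bound.

    ``lambda_max = max_i |(1/n) x_i'(y - ybar)| / max(alpha, 0.001)`` on
    standardized features; at this value the KKT conditions hold at
    beta = 0 for any alpha > 0.
    """
    y = np.asarray(y01, dtype=float)
    if np.unique(y).shape[0] < 2:
        raise ValueError("labels are constant; no signal to scale the path")
    n, p = X.shape
    Xs = _standardize(X)[0] if standardize else np.asarray(X, dtype=float)
    if lambda_min_ratio is None:
        lambda_min_ratio = 0.01 if n < p else 1e-4
    resid = y - y.mean()
    lam_max = np.max(np.abs(Xs.T @ resid)) / n / max(alpha, _ALPHA_FLOOR)
    # nudge above the exact KKT bound so rounding cannot leak a ~1-ulp
    # non-zero coefficient at the top of the path
    lam_max *= 1.0 + 1e-9
    if n_lambda == 1:
        return np.array([lam_max])
    return lam_max * np.power(
        lambda_min_ratio, np.linspace(0.0, 1.0, n_lambda)
    )


def _fit_std(Xs, y, lambdas, config):
    """Run the kernel on standardized data; returns standardized-scale path."""
    Xf = np.asfortranarray(Xs, dtype=np.float64)
    return enet_logistic_path(
        Xf,
        np.ascontiguousarray(y, dtype=np.float64),
        np.ascontiguousarray(lambdas, dtype=np.float64),
        float(config.alpha),
        float(config.tol),
        int(config.max_sweeps),
        _MAX_IRLS,
    )


def fit_path(
    X: np.ndarray,
    y01: np.ndarray,
    config: EnetConfig,
    lambdas: np.ndarray | None = None,
) -> EnetFit:
    """Fit the full lambda path (no cross-validation fields)."""
    X = np.asarray(X, dtype=float)
    y = labels_to_binary(y01) if set(np.unique(y01)) != {0, 1} else np.asarray(
        y01, dtype=float
    )
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y01 have inconsistent sample counts")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if lambdas is None:
        lambdas = lambda_path(
            X, y, config.alpha, config.n_lambda, config.lambda_min_ratio,
            config.standardize,
        )
    if np.any(np.diff(lambdas) >= 0):
        raise ValueError("lambda path must be strictly decreasing")
    if lambdas[-1] == 0.0 and X.shape[0] <= X.shape[1]:
        warnings.warn(
            "lambda = 0 with n <= p: the unpenalized logistic MLE may not "
            "exist; results can be unstable",
            stacklevel=2,
        )
    if config.standardize:
        Xs, center, scale = _standardize(X)
    else:
        Xs, center, scale = X, np.zeros(X.shape[1]), np.ones(X.shape[1])
    coefs_s, b0_s, converged, obj = _fit_std(Xs, y, lambdas, config)
    if not converged.all():
        warnings.warn(
            f"{int((~converged).sum())} path point(s) hit the sweep cap "
            f"before convergence; best iterates returned",
            stacklevel=2,
        )
    coefs = coefs_s / scale[None, :]
    intercepts = b0_s - coefs_s @ (center / scale)
    return EnetFit(
        alpha=config.alpha,
        lambda_path=np.asarray(lambdas, dtype=float),
        coef_path=coefs,
        intercept_path=intercepts,
        converged=converged,
        objective_trace=obj,
    )


def _binomial_deviance(eta: np.ndarray, y: np.ndarray) -> float:
    p = 1.0 / (1.0 + np.exp(-eta))
    p = np.clip(p, 1e-10, 1.0 - 1e-10)
    return float(-2.0 * np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _make_folds(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    idx = rng.permutation(n)
    fold = np.empty(n, dtype=int)
    fold[idx] = np.arange(n) % k
    return fold


def cv_select_lambda(
    X: np.ndarray, y01: np.ndarray, config: EnetConfig
) -> EnetFit:
    """Fit the path on the full data and choose lambda by k-fold CV.

    Folds come from a seeded unstratified shuffle; a shuffle that leaves a
    training split with one class is redrawn (up to 10 attempts).  Held-out
    loss is the mean binomial deviance (or misclassification rate) at the
    common lambda grid; ``lambda_chosen`` follows ``config.lambda_rule``.
    """
    X = np.asarray(X, dtype=float)
    y = labels_to_binary(y01) if set(np.unique(y01)) != {0, 1} else np.asarray(
        y01, dtype=float
    )
    n = X.shape[0]
    k = config.cv_folds
    if k > n:
        warnings.warn(
            f"cv_folds={k} exceeds n={n}; reduced to {n}", stacklevel=2
        )
        k = n
    rng = np.random.default_rng(config.seed)
    folds = None
    for _ in range(10):
        cand = _make_folds(n, k, rng)
        ok = all(
            np.unique(y[cand != f]).shape[0] == 2 for f in range(k)
        )
        if ok:
            folds = cand
            break
    if folds is None:
        raise ValueError(
            "could not build CV folds whose training splits contain both "
            "classes after 10 shuffles"
        )

    lambdas = lambda_path(
        X, y, config.alpha, config.n_lambda, config.lambda_min_ratio,
        config.standardize,
    )
    fit = fit_path(X, y, config, lambdas=lambdas)

    nl = lambdas.shape[0]
    fold_loss = np.empty((k, nl))
    fold_n = np.empty(k)
    for f in range(k):
        tr, te = folds != f, folds == f
        sub = fit_path(X[tr], y[tr], config, lambdas=lambdas)
        eta = sub.intercept_path[:, None] + sub.coef_path @ X[te].T
        for j in range(nl):
            if config.cv_loss == "deviance":
                fold_loss[f, j] = _binomial_deviance(eta[j], y[te])
            else:
                fold_loss[f, j] = float(
                    np.mean((eta[j] > 0).astype(float) != y[te])
                )
        fold_n[f] = te.sum()
    wts = fold_n / fold_n.sum()
    cv_mean = wts @ fold_loss
    cv_se = np.sqrt(
        np.sum(wts[:, None] * (fold_loss - cv_mean[None, :]) ** 2, axis=0)
        / (k - 1)
    )

    i_min = int(np.argmin(cv_mean))
    if config.lambda_rule == "min":
        i_chosen = i_min
    else:  # one_se: largest lambda within one SE of the minimum
        thresh = cv_mean[i_min] + cv_se[i_min]
        i_chosen = int(np.nonzero(cv_mean <= thresh)[0][0])
    fit.cv_mean = cv_mean
    fit.cv_se = cv_se
    fit.lambda_chosen = float(lambdas[i_chosen])
    fit.lambda_chosen_index = i_chosen
    return fit


def selected_set(fit: EnetFit) -> np.ndarray:
    """Boolean vector of features with non-zero coefficients at the chosen
    lambda."""
    return fit.selected


def kkt_violation(
    X: np.ndarray,
    y01: np.ndarray,
    beta0: float,
    beta: np.ndarray,
    lam: float,
    alpha: float,
) -> float:
    """Largest violation of the first-order optimality conditions.

    For zero coefficients the subgradient condition requires
    ``|(1/n) x_i'(y - p)| <= lambda * alpha``; for non-zero coefficients the
    stationarity equation must hold.  Returns the maximum violation across
    coordinates (0 at an exact optimum), computed on whatever scale
    ``X``/``beta`` are given in.
    """
    y = np.asarray(y01, dtype=float)
    n = X.shape[0]
    eta = beta0 + X @ beta
    prob = 1.0 / (1.0 + np.exp(-eta))
    grad = -(X.T @ (y - prob)) / n  # gradient of the negative log-likelihood
    grad0 = -np.mean(y - prob)
    viol = abs(grad0)
    zero = beta == 0.0
    if zero.any():
        viol = max(
            viol, float(np.max(np.abs(grad[zero])) - lam * alpha)
        )
    nz = ~zero
    if nz.any():
        stat = grad[nz] + lam * (1 - alpha) * beta[nz] + lam * alpha * np.sign(
            beta[nz]
        )
        viol = max(viol, float(np.max(np.abs(stat))))
    return viol
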