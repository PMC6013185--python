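"""Numba coordinate-descent kernel for elastic-net logistic regression.

The kernel minimizes, over a decreasing penalty path with warm starts,

    -(1/n) sum_j [ y_j eta_j - log(1 + exp(eta_j)) ]
        + lambda [ (1-alpha)/2 ||beta||_2^2 + alpha ||beta||_1 ],

with eta_j = beta0 + x_j' beta, via iteratively reweighted least squares:
each outer cycle builds the quadratic approximation at the current iterate
(weights w_j = p_j (1 - p_j), clamped probabilities) and solves the
penalized weighted least-squares subproblem by cyclic coordinate descent
with soft-thresholding, using an active-set strategy (full sweep, then
iterate on the nonzero set until converged, then a confirming full sweep).
The intercept is unpenalized.  Features are assumed standardized by the
caller; X should be Fortran-ordered for contiguous column access.
"""

from __future__ import annotations

import numpy as np
from numba import njit

PROB_CLAMP = 1e-5


@njit(cache=True, fastmath=True)
def _soft(z, g):
    if z > g:
        return z - g
    if z < -g:
        return z + g
    return 0.0


@njit(cache=True, fastmath=True)
def _sweep(X, r, w, xv, beta, beta0, wsum_n, l1, l2, active_only):
    """One coordinate-descent sweep; returns (max weighted sq change, beta0).

    ``r`` is the weighted working residual w * (z - eta) == maintained as
    y - p at the start of an outer cycle; it is updated in place as
    coefficients move.
    """
    n, p = X.shape
    maxd = 0.0
    for i in range(p):
        if active_only and beta[i] == 0.0:
            continue
        if xv[i] <= 0.0:
            continue
        num = 0.0
        for j in range(n):
            num += X[j, i] * r[j]
        num = num / n + xv[i] * beta[i]
        bnew = _soft(num, l1) / (xv[i] + l2)
        d = bnew - beta[i]
        if d != 0.0:
            for j in range(n):
                r[j] -= w[j] * X[j, i] * d
            beta[i] = bnew
            ch = xv[i] * d * d
            if ch > maxd:
                maxd = ch
    # unpenalized intercept
    if wsum_n > 0.0:
        num0 = 0.0
        for j in range(n):
            num0 += r[j]
        d0 = num0 / (n * wsum_n)
        if d0 != 0.0:
            for j in range(n):
                r[j] -= w[j] * d0
            beta0 += d0
            ch = wsum_n * d0 * d0
            if ch > maxd:
                maxd = ch
    return maxd, beta0


@njit(cache=True, fastmath=True)
def enet_logistic_path(X, y, lambdas, alpha, tol, max_sweeps, max_irls):
    """Fit the whole lambda path; returns coefficients in the given scale.

    Returns
    -------
    coefs : (n_lambda, p) coefficients
    intercepts : (n_lambda,)
    converged : (n_lambda,) bool
    obj_trace : (n_lambda, max_irls) penalized objective recorded at the
        start of each outer IRLS cycle (NaN where unused); non-increasing
        along each row up to numerical tolerance.
    """
    n, p = X.shape
    nl = lambdas.shape[0]
    coefs = np.zeros((nl, p))
    intercepts = np.zeros(nl)
    converged = np.zeros(nl, dtype=np.bool_)
    obj_trace = np.full((nl, max_irls), np.nan)

    beta = np.zeros(p)
    ybar = y.mean()
    beta0 = np.log(ybar / (1.0 - ybar))
    eta = np.empty(n)
    prob = np.empty(n)
    w = np.empty(n)
    r = np.empty(n)
    xv = np.empty(p)
    beta_start = np.empty(p)

    for k in range(nl):
        lam = lambdas[k]
        l1 = lam * alpha
        l2 = lam * (1.0 - alpha)
        sweeps = 0
        conv = False
        for it in range(max_irls):
            # rebuild the quadratic approximation at the current iterate
            for j in range(n):
                e = beta0
                for i in range(p):
                    if beta[i] != 0.0:
                        e += X[j, i] * beta[i]
                eta[j] = e
            nll = 0.0
            wsum = 0.0
            for j in range(n):
                pj = 1.0 / (1.0 + np.exp(-eta[j]))
                if pj < PROB_CLAMP:
                    pj = PROB_CLAMP
                elif pj > 1.0 - PROB_CLAMP:
                    pj = 1.0 - PROB_CLAMP
                prob[j] = pj
                w[j] = pj * (1.0 - pj)
                r[j] = y[j] - pj
                wsum += w[j]
                # stable log(1 + exp(eta))
                if eta[j] > 0.0:
                    lse = eta[j] + np.log1p(np.exp(-eta[j]))
                else:
                    lse = np.log1p(np.exp(eta[j]))
                nll += y[j] * eta[j] - lse
            l1n = 0.0
            l2n = 0.0
            for i in range(p):
                l1n += abs(beta[i])
                l2n += beta[i] * beta[i]
            obj_trace[k, it] = -nll / n + lam * (
                (1.0 - alpha) / 2.0 * l2n + alpha * l1n
            )
            wsum_n = wsum / n
            for i in range(p):
                s = 0.0
                for j in range(n):
                    s += w[j] * X[j, i] * X[j, i]
                xv[i] = s / n
            for i in range(p):
                beta_start[i] = beta[i]
            beta0_start = beta0

            # penalized WLS subproblem: full sweep / active-set cycles
            while True:
                maxd, beta0 = _sweep(
                    X, r, w, xv, beta, beta0, wsum_n, l1, l2, False
                )
                sweeps += 1
                if maxd < tol or sweeps >= max_sweeps:
                    break
                while True:
                    maxd2, beta0 = _sweep(
                        X, r, w, xv, beta, beta0, wsum_n, l1, l2, True
                    )
                    sweeps += 1
                    if maxd2 < tol or sweeps >= max_sweeps:
                        break
                if sweeps >= max_sweeps:
                    break

            dmax = wsum_n * (beta0 - beta0_start) ** 2
            for i in range(p):
                ch = xv[i] * (beta[i] - beta_start[i]) ** 2
                if ch > dmax:
                    dmax = ch
            if dmax < tol:
                conv = sweeps < max_sweeps
                break
        for i in range(p):
            coefs[k, i] = beta[i]
        intercepts[k] = beta0
        converged[k] = conv
    return coefs, intercepts, converged, obj_trace
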