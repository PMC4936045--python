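"""Adaptive Gauss-Hermite quadrature for single-factor logistic GLMMs.

With one grouping factor the marginal likelihood factorizes over groups
into one-dimensional integrals, which adaptive Gauss-Hermite quadrature
evaluates to near machine precision at modest node counts.  That makes
this module an independent, high-accuracy reference for validating the
Laplace-approximated fitter on single-factor designs; it is not used by
the analysis pipeline itself (the crossed bear x year design does not
factorize).
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import expit, logsumexp

__all__ = ["aghq_marginal_loglik", "fit_aghq"]


def _group_slices(groups: np.ndarray):
    order = np.argsort(groups, kind="stable")
    sorted_groups = groups[order]
    boundaries = np.flatnonzero(np.diff(sorted_groups)) + 1
    return [idx for idx in np.split(order, boundaries)]


def aghq_marginal_loglik(
    beta: np.ndarray,
    sigma: float,
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    n_nodes: int = 64,
) -> float:
    """Marginal log-likelihood of a random-intercept logistic model.

    ``groups`` are integer labels; the intercept variance is ``sigma**2``.
    Each group's integral over its intercept is computed by Gauss-Hermite
    quadrature recentred at the group mode and rescaled by the curvature
    there (the adaptive rule), with all products kept in log space.
    """
    if sigma <= 1e-8:  # degenerate prior: the integral collapses onto u = 0
        eta = X @ beta
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    nodes, weights = hermgauss(n_nodes)
    log_w = np.log(weights)
    eta0 = X @ beta
    total = 0.0
    s2 = sigma * sigma
    for idx in _group_slices(np.asarray(groups)):
        e0, yg = eta0[idx], y[idx]

        def f(u):
            eta = e0 + u
            return (
                np.sum(yg * eta - np.logaddexp(0.0, eta))
                - 0.5 * u * u / s2
                - 0.5 * np.log(2.0 * np.pi * s2)
            )

        # 1-D Newton for the group mode
        u = 0.0
        for _ in range(100):
            mu = expit(e0 + u)
            g = np.sum(yg - mu) - u / s2
            h = np.sum(mu * (1.0 - mu)) + 1.0 / s2
            step = g / h
            u += step
            if abs(step) < 1e-12:
                break
        mu = expit(e0 + u)
        h = np.sum(mu * (1.0 - mu)) + 1.0 / s2  # -f''(u*)
        scale = np.sqrt(2.0 / h)
        pts = u + scale * nodes
        log_terms = log_w + nodes**2 + np.array([f(pt) for pt in pts])
        total += logsumexp(log_terms) + np.log(scale)
    return float(total)


def fit_aghq(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    n_nodes: int = 64,
    beta0: np.ndarray | None = None,
    log_sigma0: float = np.log(0.3),
):
    """Maximum-likelihood fit of the single-factor model by AGHQ.

    Optimizes (beta, log sigma) with Nelder-Mead on the quadrature
    likelihood (derivative-free; the objective is smooth but cheap at the
    problem sizes this reference is used for).  Returns
    ``(beta_hat, sigma_hat, loglik)``.
    """
    p = X.shape[1]
    x0 = np.concatenate([np.zeros(p) if beta0 is None else beta0, [log_sigma0]])

    def neg(params):
        return -aghq_marginal_loglik(params[:p], np.exp(params[-1]), X, y, groups, n_nodes)

    res = optimize.minimize(
        neg, x0, method="Nelder-Mead", options={"xatol": 1e-7, "fatol": 1e-9, "maxfev": 20000}
    )
    # polish from the simplex optimum
    res = optimize.minimize(neg, res.x, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxfev": 20000})
    beta_hat = res.x[:p]
    sigma_hat = float(np.exp(res.x[-1]))
    return beta_hat, sigma_hat, float(-res.fun)
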