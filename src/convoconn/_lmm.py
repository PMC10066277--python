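"""Profiled-REML solver for the random-intercept linear mixed model.

The mass-univariate stages fit the same one-random-intercept model at every
node, thousands of times across permutation and replication experiments; a
general-purpose mixed-model fitter is orders of magnitude more machinery
than this model needs.  Here the covariance V = sigma^2 (I + rho Z Z') is
inverted in closed form per participant block (Sherman-Morrison on the
all-ones matrix), beta and sigma^2 are profiled out, and the REML criterion
is minimized over the single variance ratio rho by bounded scalar search.

Tests cross-check fixed effects and standard errors against statsmodels'
MixedLM on random problems.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar


def _precompute(y, X, groups):
    """Sufficient statistics: totals plus per-group sums of X and y."""
    n_groups = int(groups.max()) + 1
    counts = np.bincount(groups, minlength=n_groups).astype(float)
    Xs = np.zeros((n_groups, X.shape[1]))
    for j in range(X.shape[1]):
        Xs[:, j] = np.bincount(groups, weights=X[:, j], minlength=n_groups)
    ys = np.bincount(groups, weights=y, minlength=n_groups)
    return {
        "XtX": X.T @ X,
        "Xty": X.T @ y,
        "yty": float(y @ y),
        "Xs": Xs,
        "ys": ys,
        "counts": counts,
    }


def _profiled_quantities(pre, rho):
    """X'V^-1 X, X'V^-1 y, y'V^-1 y and log|V_rho| for V_rho = I + rho ZZ'."""
    c = rho / (1.0 + rho * pre["counts"])
    Xs, ys = pre["Xs"], pre["ys"]
    xtx = pre["XtX"] - (Xs * c[:, None]).T @ Xs
    xty = pre["Xty"] - Xs.T @ (c * ys)
    yty = pre["yty"] - float(c @ (ys * ys))
    logdet = float(np.sum(np.log1p(rho * pre["counts"])))
    return xtx, xty, yty, logdet


def reml_random_intercept(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    max_ratio: float = 1e4,
):
    """REML fit of y = X beta + (1|group) + e.

    groups must be an integer array; observations are re-sorted internally.
    Returns (beta, se, rho, sigma2) with rho = tau^2 / sigma^2.
    Raises np.linalg.LinAlgError on singular designs.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    _, gidx = np.unique(np.asarray(groups), return_inverse=True)
    n, p = X.shape
    if n <= p:
        raise np.linalg.LinAlgError("not enough observations")
    pre = _precompute(y, X, gidx)

    def criterion(log1p_rho):
        rho = np.expm1(log1p_rho)
        xtx, xty, yty, logdet = _profiled_quantities(pre, rho)
        sign, logdet_xtx = np.linalg.slogdet(xtx)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(xtx, xty)
        rss = yty - beta @ xty
        if rss <= 0:
            return np.inf
        return (n - p) * np.log(rss) + logdet + logdet_xtx

    res = minimize_scalar(
        criterion, bounds=(0.0, np.log1p(max_ratio)), method="bounded",
        options={"xatol": 1e-8},
    )
    rho = float(np.expm1(res.x))
    # accept the boundary rho=0 when it is as good (flat profiles)
    if criterion(0.0) <= res.fun + 1e-10:
        rho = 0.0
    xtx, xty, yty, _ = _profiled_quantities(pre, rho)
    beta = np.linalg.solve(xtx, xty)
    rss = yty - beta @ xty
    sigma2 = rss / (n - p)
    cov = sigma2 * np.linalg.inv(xtx)
    se = np.sqrt(np.diag(cov))
    return beta, se, rho, sigma2
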