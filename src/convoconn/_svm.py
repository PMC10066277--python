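"""Compiled kernels for the leave-one-out linear SVM chain.

The phenotype pipeline refits an L2-regularized hinge-loss linear classifier
once per held-out conversation, and the permutation test repeats the whole
leave-one-out chain for every relabeling.  At the scale of the permutation
calibration experiments this amounts to hundreds of thousands of small SVM
fits, so the solver here is a numba-compiled dual coordinate descent
(Hsieh et al. 2008, the algorithm used by liblinear for the L1-loss dual).

The optimization problem is liblinear's: the intercept is absorbed as an
extra feature column of constant value ``intercept_scaling`` and is therefore
penalized together with the weights,

    min_w  0.5 ||w||^2 + C * sum_i max(0, 1 - y_i w.x_i),

with x_i the augmented feature vector.  Tests cross-check decision values
against sklearn's LinearSVC and against a brute-force convex QP solution.
"""

from __future__ import annotations

import numpy as np
from numba import njit

INTERCEPT_SCALING = 1.0


@njit(cache=True)
def _dcd_hinge_from(X, y, C, tol, max_iter, seed, alpha, w):
    """Dual coordinate descent from a warm start (alpha, w modified in place).

    X must already carry the augmented intercept column.  y is +-1.
    Returns the augmented weight vector (last entry = scaled intercept).
    """
    n, d = X.shape
    qdiag = np.empty(n)
    for i in range(n):
        s = 0.0
        for k in range(d):
            s += X[i, k] * X[i, k]
        qdiag[i] = s
    index = np.arange(n)
    np.random.seed(seed)
    active = n
    pg_max_old = 1e300
    pg_min_old = -1e300
    for _ in range(max_iter):
        # Fisher-Yates shuffle of the active visiting order
        for i in range(active - 1, 0, -1):
            j = np.random.randint(0, i + 1)
            index[i], index[j] = index[j], index[i]
        pg_max = -1e300
        pg_min = 1e300
        s = 0
        while s < active:
            i = index[s]
            g = 0.0
            for k in range(d):
                g += w[k] * X[i, k]
            g = y[i] * g - 1.0
            pg = 0.0
            shrink = False
            if alpha[i] == 0.0:
                if g > pg_max_old:
                    shrink = True
                elif g < 0.0:
                    pg = g
            elif alpha[i] == C:
                if g < pg_min_old:
                    shrink = True
                elif g > 0.0:
                    pg = g
            else:
                pg = g
            if shrink:
                active -= 1
                index[s] = index[active]
                index[active] = i
                continue
            if pg > pg_max:
                pg_max = pg
            if pg < pg_min:
                pg_min = pg
            if pg > 1e-12 or pg < -1e-12:
                a_old = alpha[i]
                a_new = a_old - g / qdiag[i]
                if a_new < 0.0:
                    a_new = 0.0
                elif a_new > C:
                    a_new = C
                alpha[i] = a_new
                delta = (a_new - a_old) * y[i]
                for k in range(d):
                    w[k] += delta * X[i, k]
            s += 1
        if pg_max - pg_min <= tol:
            if active == n:
                break
            # converged on the shrunken set: unshrink and verify
            active = n
            pg_max_old = 1e300
            pg_min_old = -1e300
            continue
        pg_max_old = pg_max if pg_max > 0.0 else 1e300
        pg_min_old = pg_min if pg_min < 0.0 else -1e300
    return w


@njit(cache=True)
def _dcd_hinge(X, y, C, tol, max_iter, seed):
    """Cold-start dual coordinate descent (see _dcd_hinge_from)."""
    n, d = X.shape
    return _dcd_hinge_from(X, y, C, tol, max_iter, seed, np.zeros(n), np.zeros(d))


@njit(cache=True)
def _loo_decision_values(X, y, C, tol, max_iter, seed):
    """Signed decision value for each row when it is held out of training.

    Each fold's dual solve is warm-started from the full-data solution
    (with the held-out point's dual contribution removed), which typically
    converges in a few sweeps; the optimum reached is the same as a cold
    start to within the solver tolerance.
    """
    n, d = X.shape
    out = np.empty(n)
    Xtr = np.empty((n - 1, d))
    ytr = np.empty(n - 1)
    alpha_full = np.zeros(n)
    w_full = _dcd_hinge_from(X, y, C, tol, max_iter, seed, alpha_full, np.zeros(d))
    alpha_tr = np.empty(n - 1)
    w = np.empty(d)
    for i in range(n):
        r = 0
        for j in range(n):
            if j == i:
                continue
            for k in range(d):
                Xtr[r, k] = X[j, k]
            ytr[r] = y[j]
            alpha_tr[r] = alpha_full[j]
            r += 1
        for k in range(d):
            w[k] = w_full[k] - alpha_full[i] * y[i] * X[i, k]
        wi = _dcd_hinge_from(Xtr, ytr, C, tol, max_iter, seed + i, alpha_tr, w)
        f = 0.0
        for k in range(d):
            f += wi[k] * X[i, k]
        out[i] = f
    return out


@njit(cache=True)
def _platt_fit(decision_values, label, max_iter=200, min_step=1e-10, sigma=1e-12):
    """Two-parameter sigmoid (Platt) calibration, Lin et al. (2007) Newton method.

    label is 1 for the positive (control-like) class, 0 otherwise.  Returns
    (A, B) such that P(positive | f) = 1 / (1 + exp(A*f + B)).
    """
    n = decision_values.shape[0]
    prior1 = 0.0
    for i in range(n):
        prior1 += label[i]
    prior0 = n - prior1
    hi = (prior1 + 1.0) / (prior1 + 2.0)
    lo = 1.0 / (prior0 + 2.0)
    t = np.empty(n)
    for i in range(n):
        t[i] = hi if label[i] > 0.5 else lo
    A = 0.0
    B = np.log((prior0 + 1.0) / (prior1 + 1.0))
    # current objective
    fval = 0.0
    for i in range(n):
        z = decision_values[i] * A + B
        if z >= 0:
            fval += t[i] * z + np.log(1.0 + np.exp(-z))
        else:
            fval += (t[i] - 1.0) * z + np.log(1.0 + np.exp(z))
    for _ in range(max_iter):
        h11 = sigma
        h22 = sigma
        h21 = 0.0
        g1 = 0.0
        g2 = 0.0
        for i in range(n):
            z = decision_values[i] * A + B
            if z >= 0:
                q = np.exp(-z) / (1.0 + np.exp(-z))
                p = 1.0 - q
            else:
                p = np.exp(z) / (1.0 + np.exp(z))
                q = 1.0 - p
            d1 = t[i] - q  # note: P(pos) = 1 - p(z); gradient wrt (A,B)
            d2 = p * q
            g1 += decision_values[i] * d1
            g2 += d1
            h11 += decision_values[i] * decision_values[i] * d2
            h22 += d2
            h21 += decision_values[i] * d2
        if abs(g1) < 1e-5 and abs(g2) < 1e-5:
            break
        det = h11 * h22 - h21 * h21
        dA = -(h22 * g1 - h21 * g2) / det
        dB = -(-h21 * g1 + h11 * g2) / det
        gd = g1 * dA + g2 * dB
        stepsize = 1.0
        ok = False
        while stepsize >= min_step:
            newA = A + stepsize * dA
            newB = B + stepsize * dB
            newf = 0.0
            for i in range(n):
                z = decision_values[i] * newA + newB
                if z >= 0:
                    newf += t[i] * z + np.log(1.0 + np.exp(-z))
                else:
                    newf += (t[i] - 1.0) * z + np.log(1.0 + np.exp(z))
            if newf < fval + 1e-4 * stepsize * gd:
                A = newA
                B = newB
                fval = newf
                ok = True
                break
            stepsize *= 0.5
        if not ok:
            break
    return A, B


def platt_predict(decision_values: np.ndarray, A: float, B: float) -> np.ndarray:
    """Apply a fitted sigmoid; output clipped strictly inside (0, 1)."""
    z = np.asarray(decision_values, dtype=float) * A + B
    p = np.where(z >= 0, np.exp(-z) / (1.0 + np.exp(-z)), 1.0 / (1.0 + np.exp(z)))
    return np.clip(p, 1e-12, 1.0 - 1e-12)


def augment(X: np.ndarray) -> np.ndarray:
    """Append the constant intercept column liblinear-style."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    ones = np.full((X.shape[0], 1), INTERCEPT_SCALING)
    return np.ascontiguousarray(np.hstack([X, ones]))


def fit_hinge_svm(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 20000,
    seed: int = 0,
) -> np.ndarray:
    """Fit on unaugmented X with labels +-1; return (coef..., intercept)."""
    Xa = augment(X)
    w = _dcd_hinge(Xa, np.ascontiguousarray(y, dtype=np.float64), C, tol, max_iter, seed)
    w[-1] *= INTERCEPT_SCALING
    return w


def loo_decision_values(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 20000,
    seed: int = 0,
) -> np.ndarray:
    Xa = augment(X)
    return _loo_decision_values(
        Xa, np.ascontiguousarray(y, dtype=np.float64), C, tol, max_iter, seed
    )


def fit_platt(decision_values: np.ndarray, positive: np.ndarray) -> tuple[float, float]:
    """Fit the sigmoid on pooled cross-validated decision values.

    positive: boolean/0-1 array, 1 = positive (control-like) class.
    """
    return _platt_fit(
        np.ascontiguousarray(decision_values, dtype=np.float64),
        np.ascontiguousarray(positive, dtype=np.float64),
    )
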