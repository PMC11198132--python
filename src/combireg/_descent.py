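"""Numba coordinate-descent kernels for elastic-net GLM paths.

Objective scaling follows the usual path-solver convention:

* gaussian:  (1/2n)·RSS + lam·sum_j[(1-alpha)/2·b_j^2 + alpha·|b_j|]
* binomial:  (1/n)·negative log-likelihood + same penalty

The intercept is never penalised. Binomial fits use iteratively reweighted
least squares with an inner weighted coordinate descent (glmnet-style).
Each lambda alternates full passes over all features with cheaper passes
restricted to the currently active (nonzero) set.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: probability floor inside the IRLS weights / likelihood
_P_EPS = 1e-9


@njit(cache=True, fastmath=True)
def _soft(x: float, t: float) -> float:
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


@njit(cache=True, fastmath=True)
def _penalty(b: np.ndarray, lam: float, alpha: float) -> float:
    s = 0.0
    for j in range(b.shape[0]):
        s += (1.0 - alpha) * 0.5 * b[j] * b[j] + alpha * abs(b[j])
    return lam * s


@njit(cache=True, fastmath=True)
def _gaussian_objective(r: np.ndarray, b: np.ndarray, lam: float, alpha: float) -> float:
    n = r.shape[0]
    s = 0.0
    for i in range(n):
        s += r[i] * r[i]
    return 0.5 * s / n + _penalty(b, lam, alpha)


@njit(cache=True, fastmath=True)
def _binomial_objective(
    eta: np.ndarray, z: np.ndarray, b: np.ndarray, lam: float, alpha: float
) -> float:
    n = eta.shape[0]
    s = 0.0
    for i in range(n):
        p = 1.0 / (1.0 + np.exp(-eta[i]))
        if p < _P_EPS:
            p = _P_EPS
        elif p > 1.0 - _P_EPS:
            p = 1.0 - _P_EPS
        s -= z[i] * np.log(p) + (1.0 - z[i]) * np.log(1.0 - p)
    return s / n + _penalty(b, lam, alpha)


@njit(cache=True, fastmath=True)
def _gaussian_sweep(
    X: np.ndarray,
    r: np.ndarray,
    b: np.ndarray,
    v: np.ndarray,
    active: np.ndarray,
    l1: float,
    l2: float,
    full: bool,
) -> float:
    """One coordinate pass; returns the largest absolute coefficient update."""
    n, p = X.shape
    maxd = 0.0
    for j in range(p):
        if not (full or active[j]):
            continue
        s = 0.0
        for i in range(n):
            s += X[i, j] * r[i]
        rho = s / n + v[j] * b[j]
        bj = _soft(rho, l1) / (v[j] + l2)
        d = bj - b[j]
        if d != 0.0:
            for i in range(n):
                r[i] -= X[i, j] * d
            b[j] = bj
            active[j] = bj != 0.0
            if abs(d) > maxd:
                maxd = abs(d)
    return maxd


@njit(cache=True, fastmath=True)
def gaussian_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    alpha: float,
    tol: float,
    max_passes: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Warm-started coordinate descent over a decreasing lambda sequence."""
    n, p = X.shape
    L = lambdas.shape[0]
    intercepts = np.zeros(L)
    coefs = np.zeros((L, p))
    b = np.zeros(p)
    active = np.zeros(p, dtype=np.bool_)
    b0 = 0.0
    for i in range(n):
        b0 += y[i]
    b0 /= n
    r = y - b0
    v = np.zeros(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += X[i, j] * X[i, j]
        v[j] = s / n
    for l in range(L):
        lam = lambdas[l]
        l1 = lam * alpha
        l2 = lam * (1.0 - alpha)
        obj = _gaussian_objective(r, b, lam, alpha)
        passes = 0
        while passes < max_passes:
            # full pass admits new coordinates and certifies optimality
            _gaussian_sweep(X, r, b, v, active, l1, l2, True)
            passes += 1
            mr = 0.0
            for i in range(n):
                mr += r[i]
            mr /= n
            if mr != 0.0:
                b0 += mr
                for i in range(n):
                    r[i] -= mr
            new_obj = _gaussian_objective(r, b, lam, alpha)
            done = abs(obj - new_obj) <= tol * (abs(obj) + 1e-12)
            obj = new_obj
            if done:
                break
            # cheap active-set passes, themselves stopped by objective change
            while passes < max_passes:
                _gaussian_sweep(X, r, b, v, active, l1, l2, False)
                passes += 1
                mr = 0.0
                for i in range(n):
                    mr += r[i]
                mr /= n
                if mr != 0.0:
                    b0 += mr
                    for i in range(n):
                        r[i] -= mr
                new_obj = _gaussian_objective(r, b, lam, alpha)
                conv = abs(obj - new_obj) <= tol * (abs(obj) + 1e-12)
                obj = new_obj
                if conv:
                    break
        intercepts[l] = b0
        coefs[l] = b
    return intercepts, coefs


@njit(cache=True, fastmath=True)
def _weighted_objective(
    w: np.ndarray, r: np.ndarray, b: np.ndarray, lam: float, alpha: float
) -> float:
    n = r.shape[0]
    s = 0.0
    for i in range(n):
        s += w[i] * r[i] * r[i]
    return 0.5 * s / n + _penalty(b, lam, alpha)


@njit(cache=True, fastmath=True)
def _weighted_sweep(
    X: np.ndarray,
    w: np.ndarray,
    r: np.ndarray,
    b: np.ndarray,
    vw: np.ndarray,
    active: np.ndarray,
    l1: float,
    l2: float,
    full: bool,
) -> float:
    n, p = X.shape
    maxd = 0.0
    for j in range(p):
        if not (full or active[j]):
            continue
        s = 0.0
        for i in range(n):
            s += w[i] * X[i, j] * r[i]
        rho = s / n + vw[j] * b[j]
        bj = _soft(rho, l1) / (vw[j] + l2)
        d = bj - b[j]
        if d != 0.0:
            for i in range(n):
                r[i] -= X[i, j] * d
            b[j] = bj
            active[j] = bj != 0.0
            if abs(d) > maxd:
                maxd = abs(d)
    return maxd


@njit(cache=True, fastmath=True)
def binomial_path(
    X: np.ndarray,
    z: np.ndarray,
    lambdas: np.ndarray,
    alpha: float,
    tol: float,
    max_passes: int,
) -> tuple[np.ndarray, np.ndarray]:
    """IRLS + weighted coordinate descent over a decreasing lambda sequence."""
    n, p = X.shape
    L = lambdas.shape[0]
    intercepts = np.zeros(L)
    coefs = np.zeros((L, p))
    b = np.zeros(p)
    active = np.zeros(p, dtype=np.bool_)
    zbar = 0.0
    for i in range(n):
        zbar += z[i]
    zbar /= n
    b0 = np.log(zbar / (1.0 - zbar))
    eta = np.full(n, b0)
    w = np.zeros(n)
    r = np.zeros(n)
    vw = np.zeros(p)
    for l in range(L):
        lam = lambdas[l]
        l1 = lam * alpha
        l2 = lam * (1.0 - alpha)
        obj = _binomial_objective(eta, z, b, lam, alpha)
        for _outer in range(100):
            # quadratic approximation at the current linear predictor
            wsum = 0.0
            for i in range(n):
                pi = 1.0 / (1.0 + np.exp(-eta[i]))
                if pi < _P_EPS:
                    pi = _P_EPS
                elif pi > 1.0 - _P_EPS:
                    pi = 1.0 - _P_EPS
                wi = pi * (1.0 - pi)
                w[i] = wi
                wsum += wi
                # residual of the working response u = eta + (z-p)/w
                r[i] = (z[i] - pi) / wi
            wsum /= n
            for j in range(p):
                s = 0.0
                for i in range(n):
                    s += w[i] * X[i, j] * X[i, j]
                vw[j] = s / n
            # solve the weighted least-squares subproblem by the same
            # full-pass / active-pass alternation, stopping on the change
            # of the quadratic objective
            qobj = _weighted_objective(w, r, b, lam, alpha)
            passes = 0
            while passes < max_passes:
                _weighted_sweep(X, w, r, b, vw, active, l1, l2, True)
                passes += 1
                s = 0.0
                for i in range(n):
                    s += w[i] * r[i]
                d0 = s / (n * wsum)
                if d0 != 0.0:
                    b0 += d0
                    for i in range(n):
                        r[i] -= d0
                new_q = _weighted_objective(w, r, b, lam, alpha)
                qdone = abs(qobj - new_q) <= tol * (abs(qobj) + 1e-12)
                qobj = new_q
                if qdone:
                    break
                while passes < max_passes:
                    _weighted_sweep(X, w, r, b, vw, active, l1, l2, False)
                    passes += 1
                    s = 0.0
                    for i in range(n):
                        s += w[i] * r[i]
                    d0 = s / (n * wsum)
                    if d0 != 0.0:
                        b0 += d0
                        for i in range(n):
                            r[i] -= d0
                    new_q = _weighted_objective(w, r, b, lam, alpha)
                    qconv = abs(qobj - new_q) <= tol * (abs(qobj) + 1e-12)
                    qobj = new_q
                    if qconv:
                        break
            for i in range(n):
                s = b0
                for j in range(p):
                    if b[j] != 0.0:
                        s += X[i, j] * b[j]
                eta[i] = s
            new_obj = _binomial_objective(eta, z, b, lam, alpha)
            done = abs(obj - new_obj) <= tol * (abs(obj) + 1e-12)
            obj = new_obj
            if done:
                break
        intercepts[l] = b0
        coefs[l] = b
    return intercepts, coefs
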