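"""Compiled coordinate-descent kernels for the penalized solvers.

Two problems are solved here, both by cyclic coordinate descent with
soft-thresholding and an active-set strategy (full sweeps alternate with
sweeps over the current nonzeros until a full sweep moves no coordinate
by more than the tolerance):

* quadratic l1: min_v  0.5 v'Wv - d'v + lam*||v||_1   (W SPD)
* lasso:        min_w  (c/(2n))*||r - Xw||^2 + lam*||w||_1

For the discriminant problem W has the form A'A/n + gamma*I with A an
n x p centered data matrix and n << p; the factored kernel works through
the n-dimensional image u = A v, so a coordinate update costs O(n)
rather than O(p). Kernels mutate their warm-start argument in place and
return (sweeps_used, converged).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "cd_quadratic_l1",
    "cd_quadratic_l1_factored",
    "cd_lasso",
    "soft_threshold",
]


@njit(cache=False)
def _soft(z: float, lam: float) -> float:
    if z > lam:
        return z - lam
    if z < -lam:
        return z + lam
    return 0.0


def soft_threshold(z: float, lam: float) -> float:
    """Scalar soft-thresholding operator sign(z)*max(|z|-lam, 0)."""
    return float(np.sign(z) * max(abs(z) - lam, 0.0))


@njit(cache=False)
def _quad_sweep(W, d, lam, v, g, active_only):
    p = W.shape[0]
    max_delta = 0.0
    for j in range(p):
        old = v[j]
        if active_only and old == 0.0:
            continue
        z = d[j] - g[j] + W[j, j] * old
        new = _soft(z, lam) / W[j, j]
        if new != old:
            delta = new - old
            for k in range(p):
                g[k] += W[k, j] * delta
            v[j] = new
            if abs(delta) > max_delta:
                max_delta = abs(delta)
    return max_delta


@njit(cache=False)
def cd_quadratic_l1(W, d, lam, v, tol, max_sweeps):
    """Cyclic CD for 0.5 v'Wv - d'v + lam||v||_1 on a dense W; v in place.

    Maintains g = Wv incrementally; the coordinate update is
    v_j <- soft(d_j - g_j + W_jj v_j, lam) / W_jj. Converged when a full
    sweep changes no coordinate by more than tol.
    """
    g = W @ v
    sweeps = 0
    while sweeps < max_sweeps:
        max_delta = _quad_sweep(W, d, lam, v, g, False)
        sweeps += 1
        if max_delta < tol:
            return sweeps, True
        while sweeps < max_sweeps:
            max_delta = _quad_sweep(W, d, lam, v, g, True)
            sweeps += 1
            if max_delta < tol:
                break
    return max_sweeps, False


@njit(cache=False)
def _quad_sweep_factored(At, gamma, d, lam, v, u, diag, n, active_only):
    p = At.shape[0]
    max_delta = 0.0
    for j in range(p):
        old = v[j]
        if active_only and old == 0.0:
            continue
        aj_u = 0.0
        for i in range(n):
            aj_u += At[j, i] * u[i]
        g_j = aj_u / n + gamma * old
        z = d[j] - g_j + diag[j] * old
        new = _soft(z, lam) / diag[j]
        if new != old:
            delta = new - old
            for i in range(n):
                u[i] += At[j, i] * delta
            v[j] = new
            if abs(delta) > max_delta:
                max_delta = abs(delta)
    return max_delta


@njit(cache=False)
def cd_quadratic_l1_factored(At, gamma, d, lam, v, tol, max_sweeps):
    """Same problem with W = A'A/n + gamma*I given via At = A' (p x n).

    Works through u = A v so each coordinate update is O(n); exact same
    iterates (up to floating-point accumulation) as the dense kernel.
    """
    p, n = At.shape
    u = np.zeros(n)
    for j in range(p):
        if v[j] != 0.0:
            for i in range(n):
                u[i] += At[j, i] * v[j]
    diag = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += At[j, i] * At[j, i]
        diag[j] = s / n + gamma
    sweeps = 0
    while sweeps < max_sweeps:
        max_delta = _quad_sweep_factored(At, gamma, d, lam, v, u, diag, n, False)
        sweeps += 1
        if max_delta < tol:
            return sweeps, True
        while sweeps < max_sweeps:
            max_delta = _quad_sweep_factored(At, gamma, d, lam, v, u, diag, n, True)
            sweeps += 1
            if max_delta < tol:
                break
    return max_sweeps, False


@njit(cache=False)
def _lasso_sweep(Xt, resid, col_sq, cn, lam, w, active_only):
    p = Xt.shape[0]
    n = Xt.shape[1]
    max_delta = 0.0
    for j in range(p):
        if col_sq[j] == 0.0:
            continue
        old = w[j]
        if active_only and old == 0.0:
            continue
        rho = 0.0
        for i in range(n):
            rho += Xt[j, i] * resid[i]
        z = cn * rho + cn * col_sq[j] * old
        new = _soft(z, lam) / (cn * col_sq[j])
        if new != old:
            delta = new - old
            for i in range(n):
                resid[i] -= Xt[j, i] * delta
            w[j] = new
            if abs(delta) > max_delta:
                max_delta = abs(delta)
    return max_delta


@njit(cache=False)
def cd_lasso(X, r_target, c, lam, w, tol, max_sweeps):
    """Cyclic CD for (c/(2n))||r_target - Xw||^2 + lam||w||_1; w in place."""
    n, p = X.shape
    Xt = np.ascontiguousarray(X.T)
    resid = r_target - X @ w
    col_sq = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += Xt[j, i] * Xt[j, i]
        col_sq[j] = s
    cn = c / n
    sweeps = 0
    while sweeps < max_sweeps:
        max_delta = _lasso_sweep(Xt, resid, col_sq, cn, lam, w, False)
        sweeps += 1
        if max_delta < tol:
            return sweeps, True
        while sweeps < max_sweeps:
            max_delta = _lasso_sweep(Xt, resid, col_sq, cn, lam, w, True)
            sweeps += 1
            if max_delta < tol:
                break
    return max_sweeps, False
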