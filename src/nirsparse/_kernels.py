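"""Compiled inner loops: cyclic coordinate descent and PLS1-NIPALS.

These kernels carry the per-coordinate / per-component work that dominates
the replication benchmarks.  They operate purely on ndarrays; all
validation, bookkeeping and object construction happens in the calling
modules.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def enet_cd(G, Xty, lambda1, lambda2, beta, max_sweeps, tol):
    """Cyclic coordinate descent on the naive elastic net objective.

    Minimizes ``||y - X b||^2 + lambda2 ||b||^2 + lambda1 ||b||_1`` given the
    Gram matrix ``G = X'X`` and covariance vector ``Xty = X'y``.  ``beta`` is
    updated in place (warm starts welcome).  Returns ``(sweeps, converged)``
    where convergence means the largest coefficient change in a full sweep
    fell below ``tol``.
    """
    p = beta.shape[0]
    c = Xty - G @ beta  # residual covariances given current beta
    half = 0.5 * lambda1
    for sweep in range(max_sweeps):
        delta_max = 0.0
        for j in range(p):
            gjj = G[j, j]
            z = c[j] + gjj * beta[j]
            if z > half:
                b = (z - half) / (gjj + lambda2)
            elif z < -half:
                b = (z + half) / (gjj + lambda2)
            else:
                b = 0.0
            d = b - beta[j]
            if d != 0.0:
                for k in range(p):
                    c[k] -= G[k, j] * d
                beta[j] = b
                ad = abs(d)
                if ad > delta_max:
                    delta_max = ad
        if delta_max < tol:
            return sweep + 1, True
    return max_sweeps, False


@njit(cache=True)
def pls1_beta(X, y, K, tol):
    """PLS1 by NIPALS; returns ``(beta, k_used)`` for ``K`` components.

    Classic recursion: weight = X'y of the deflated data, normalized; score
    t = Xw; X and y are deflated by the score's projection.  The regression
    vector mapping the *original* X to fitted y is ``W (P'W)^{-1} q``.
    Stops early when the residual covariance vanishes (k_used < K).
    """
    n, p = X.shape
    Xd = X.copy()
    yd = y.copy()
    W = np.zeros((p, K))
    P = np.zeros((p, K))
    q = np.zeros(K)
    k_used = 0
    for k in range(K):
        w = Xd.T @ yd
        nw = np.sqrt(np.sum(w * w))
        if nw <= tol:
            break
        w = w / nw
        t = Xd @ w
        tt = np.sum(t * t)
        if tt <= tol * tol:
            break
        pk = (Xd.T @ t) / tt
        qk = np.dot(t, yd) / tt
        Xd -= np.outer(t, pk)
        yd -= qk * t
        W[:, k] = w
        P[:, k] = pk
        q[k] = qk
        k_used = k + 1
    beta = np.zeros(p)
    if k_used > 0:
        Wk = np.ascontiguousarray(W[:, :k_used])
        Pk = np.ascontiguousarray(P[:, :k_used])
        A = Pk.T @ Wk
        beta = Wk @ np.linalg.solve(A, np.ascontiguousarray(q[:k_used]))
    return beta, k_used
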