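"""Independent brute-force oracles: naive per-pair / per-entry scalar loops.

These deliberately avoid the vectorized code paths they check.
"""

from __future__ import annotations

import math

import numpy as np


def naive_metric(x, y, metric: str, inv_scale=None) -> float:
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    if metric == "tfunction":
        xy = sum(a * b for a, b in zip(x, y))
        xx = sum(a * a for a in x)
        yy = sum(b * b for b in y)
        rad = xx + yy - abs(xy)
        return xy / math.sqrt(rad) if rad > 0 else 0.0
    if metric == "euclidean":
        return -math.sqrt(sum((a - b) ** 2 for a, b in zip(x, y)))
    if metric == "squared_euclidean":
        return -sum((a - b) ** 2 for a, b in zip(x, y))
    if metric == "standardized_euclidean":
        return -math.sqrt(sum(((a - b) * w) ** 2
                              for a, b, w in zip(x, y, inv_scale)))
    if metric == "cityblock":
        return -sum(abs(a - b) for a, b in zip(x, y))
    if metric == "chebychev":
        return -max(abs(a - b) for a, b in zip(x, y))
    if metric == "cosine":
        nx = math.sqrt(sum(a * a for a in x))
        ny = math.sqrt(sum(b * b for b in y))
        if nx == 0 or ny == 0:
            return 0.0
        return sum(a * b for a, b in zip(x, y)) / (nx * ny)
    if metric == "pearson":
        mx = sum(x) / len(x)
        my = sum(y) / len(y)
        return naive_metric([a - mx for a in x], [b - my for b in y], "cosine")
    raise ValueError(metric)


def naive_pairwise(X, Y, metric: str) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    inv_scale = None
    if metric == "standardized_euclidean":
        stacked = np.vstack([X, Y])
        s = stacked.std(axis=0, ddof=1)
        inv_scale = [1.0 / v if v > 0 else 0.0 for v in s]
    out = np.empty((X.shape[0], Y.shape[0]))
    for i in range(X.shape[0]):
        for j in range(Y.shape[0]):
            out[i, j] = naive_metric(X[i], Y[j], metric, inv_scale)
    return out


def naive_zrows(S: np.ndarray) -> np.ndarray:
    out = np.zeros_like(S, dtype=float)
    for i in range(S.shape[0]):
        row = S[i]
        m = row.mean()
        s = row.std(ddof=1)
        if s > 0:
            out[i] = (row - m) / s
    return out


def naive_update_diagonal(M: np.ndarray, alpha: float, k: int) -> np.ndarray:
    out = np.array(M, dtype=float, copy=True)
    n = M.shape[0]
    for i in range(n):
        off = [M[i, j] for j in range(n) if j != i]
        std = float(np.std(off, ddof=0)) if off else 0.0
        out[i, i] = n * std * math.exp(2.0 * alpha * k)
    return out


def naive_panda_step(W, P, C, alpha: float, metric: str, k: int,
                     state_caps=None):
    """Scalar re-implementation of one message-passing update.

    Returns (W_next, P_next, C_next, R, A, hamming).
    """
    scale_homog = {"euclidean", "squared_euclidean", "cityblock", "chebychev"}
    caps = state_caps or {"euclidean": 1e12, "chebychev": 1e12,
                          "squared_euclidean": 1e6, "cityblock": 1e6}
    W = np.asarray(W, dtype=float)
    P = np.asarray(P, dtype=float)
    C = np.asarray(C, dtype=float)
    R = naive_pairwise(P, W.T, metric)
    A = naive_pairwise(W, C.T, metric)
    if metric in scale_homog:
        R = naive_zrows(R)
        A = naive_zrows(A.T).T
    upd = (R + A) / 2.0
    hamming = float(np.mean(np.abs(W - upd)))
    W2 = (1.0 - alpha) * W + alpha * upd
    Pu = naive_update_diagonal(naive_pairwise(W2, W2, metric), alpha, k)
    P2 = (1.0 - alpha) * P + alpha * Pu
    Cu = naive_update_diagonal(naive_pairwise(W2.T, W2.T, metric), alpha, k)
    C2 = (1.0 - alpha) * C + alpha * Cu
    if metric in scale_homog:
        cap = caps[metric]
        mP = float(np.abs(P2).max())
        if mP > cap:
            P2 = P2 * (cap / mP)
        mC = float(np.abs(C2).max())
        if mC > cap:
            C2 = C2 * (cap / mC)
    return W2, P2, C2, R, A, hamming


def naive_pearson_matrix(X: np.ndarray) -> np.ndarray:
    """Per-pair Pearson correlation of rows, plain loops."""
    X = np.asarray(X, dtype=float)
    g = X.shape[0]
    out = np.zeros((g, g))
    for i in range(g):
        for j in range(g):
            if i == j:
                out[i, j] = 1.0
                continue
            xi, xj = X[i], X[j]
            si, sj = xi.std(ddof=1), xj.std(ddof=1)
            if si == 0 or sj == 0:
                out[i, j] = 0.0
            else:
                cov = float(np.sum((xi - xi.mean()) * (xj - xj.mean()))) / (len(xi) - 1)
                out[i, j] = cov / (si * sj)
    return out
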