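"""Pairwise profile similarity: the Tfunction and seven alternative metrics.

The message-passing update scores every TF-gene pair by comparing two
profile vectors.  The default score is a modified Tanimoto similarity for
continuous vectors,

    t(x, y) = x.y / sqrt(x.x + y.y - |x.y|),

which is positively homogeneous of degree 1 (t(cx, cy) = c t(x, y) for
c > 0) and satisfies t(x, x) = ||x||.  Seven conventional metrics are
provided as alternatives.  Distances (euclidean, squared_euclidean,
standardized_euclidean, cityblock, chebychev) are returned NEGATED so that
larger always means more similar; cosine and pearson are similarities
already and are returned as-is in [-1, 1].
"""

from __future__ import annotations

import numpy as np

__all__ = ["METRICS", "tfunction", "pairwise_similarity"]

METRICS = (
    "tfunction",
    "euclidean",
    "squared_euclidean",
    "standardized_euclidean",
    "cityblock",
    "chebychev",
    "cosine",
    "pearson",
)


def _check_inner(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.atleast_2d(np.asarray(X))
    Y = np.atleast_2d(np.asarray(Y))
    if X.shape[1] != Y.shape[1]:
        raise ValueError(
            f"inner dimension mismatch: X has {X.shape[1]} columns, Y has {Y.shape[1]}"
        )
    return X, Y


def tfunction(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Modified Tanimoto similarity between every row of X and every row of Y.

    Entries whose denominator radicand x.x + y.y - |x.y| is <= 0 (possible
    only through floating-point cancellation, e.g. in single precision) are
    set to 0, the neutral similarity.
    """
    X, Y = _check_inner(X, Y)
    with np.errstate(divide="ignore", invalid="ignore"):
        XY = X @ Y.T
        xx = np.einsum("ij,ij->i", X, X)
        yy = np.einsum("ij,ij->i", Y, Y)
        radicand = xx[:, None] + yy[None, :] - np.abs(XY)
        ok = radicand > 0
        out = XY / np.sqrt(np.where(ok, radicand, 1.0))
    return np.where(ok, out, np.zeros((), dtype=out.dtype))


def _sq_euclidean(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    # accumulate (x-y)^2 directly rather than via xx+yy-2xy: the inner-product
    # form loses the "zero iff identical" guarantee to cancellation
    return _abs_diff_reduce(X, Y, lambda d, axis: np.sum(d * d, axis=axis))


def _abs_diff_reduce(X: np.ndarray, Y: np.ndarray, reducer) -> np.ndarray:
    # chunk rows of X to bound the a*b*k temporary
    out = np.empty((X.shape[0], Y.shape[0]), dtype=np.result_type(X, Y))
    step = max(1, int(2**22 // max(1, Y.size)))
    for lo in range(0, X.shape[0], step):
        hi = min(lo + step, X.shape[0])
        out[lo:hi] = reducer(np.abs(X[lo:hi, None, :] - Y[None, :, :]), axis=2)
    return out


def pairwise_similarity(X: np.ndarray, Y: np.ndarray, metric: str = "tfunction") -> np.ndarray:
    """Similarity between all row profiles of X and all row profiles of Y.

    Returns an ``(a, b)`` matrix for ``X`` of shape ``(a, k)`` and ``Y`` of
    shape ``(b, k)``.  Metric names are case-insensitive.  For
    ``standardized_euclidean`` each coordinate is scaled by its pooled
    standard deviation (ddof=1) over the stacked rows of X and Y;
    zero-variance coordinates are dropped (weight 0).
    """
    name = str(metric).lower()
    if name not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; valid metrics: {', '.join(METRICS)}")
    X, Y = _check_inner(X, Y)

    if name == "tfunction":
        return tfunction(X, Y)
    if name == "squared_euclidean":
        return -_sq_euclidean(X, Y)
    if name == "euclidean":
        return -np.sqrt(_sq_euclidean(X, Y))
    if name == "standardized_euclidean":
        stacked = np.vstack([X, Y])
        s = stacked.std(axis=0, ddof=1)
        inv = np.where(s > 0, 1.0 / np.where(s > 0, s, 1.0), 0.0)
        return -np.sqrt(_sq_euclidean(X * inv, Y * inv))
    if name == "cityblock":
        return -_abs_diff_reduce(X, Y, np.sum)
    if name == "chebychev":
        return -_abs_diff_reduce(X, Y, np.max)
    if name == "cosine":
        nx = np.sqrt(np.einsum("ij,ij->i", X, X))
        ny = np.sqrt(np.einsum("ij,ij->i", Y, Y))
        denom = np.outer(nx, ny)
        ok = denom > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            out = (X @ Y.T) / np.where(ok, denom, 1.0)
        return np.where(ok, out, np.zeros((), dtype=out.dtype))
    # pearson: cosine of the row-centered profiles
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    nx = np.sqrt(np.einsum("ij,ij->i", Xc, Xc))
    ny = np.sqrt(np.einsum("ij,ij->i", Yc, Yc))
    denom = np.outer(nx, ny)
    ok = denom > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (Xc @ Yc.T) / np.where(ok, denom, 1.0)
    return np.where(ok, out, np.zeros((), dtype=out.dtype))
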