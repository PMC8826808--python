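"""Full-sample and leave-one-out co-expression via rank-one downdates.

Estimating one network per sample (LIONESS) requires the gene-gene Pearson
correlation matrix with each sample left out in turn.  Recomputing it from
scratch costs O(g^2 n) per sample; instead, the mean vector m, std vector s
and covariance matrix Cov are computed once over all n samples and each
sample-deprived matrix is recovered by a rank-one downdate:

    m_i   = (n m - G_i) / (n - 1)
    s_i^2 = ((n-1) s^2 - n/(n-1) (G_i - m)^2) / (n - 2)
    Cov_i = ((n-1) Cov - n/(n-1) (G_i - m)(G_i - m)') / (n - 2)
    C_i   = Cov_i / (s_i s_i')

with all variances/covariances using ddof=1 — the convention the
(n-1)/(n-2) structure requires.  Every on-line quantity must agree with
direct recomputation on the n-1 retained samples to 1e-10; the direct path
is kept as the oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import ExpressionMatrix, _pearson_rows

__all__ = [
    "MomentSummary",
    "LeaveOneOutMoments",
    "init_moments",
    "loo_mean",
    "loo_std",
    "loo_cov",
    "loo_coexpression",
    "direct_loo_coexpression",
]


def _values(expr) -> np.ndarray:
    return expr.values if isinstance(expr, ExpressionMatrix) else np.asarray(expr, dtype=float)


@dataclass
class MomentSummary:
    """All-sample moments: the once-computed basis of every downdate."""

    n: int
    m: np.ndarray
    s: np.ndarray
    Cov: np.ndarray


@dataclass
class LeaveOneOutMoments:
    i: int
    m_i: np.ndarray
    s_i: np.ndarray
    Cov_i: np.ndarray


def init_moments(expr) -> MomentSummary:
    """One pass over the gene-by-sample matrix: mean, std, covariance (ddof=1)."""
    X = _values(expr)
    n = X.shape[1]
    if n < 3:
        raise ValueError(f"leave-one-out moments need at least 3 samples, got {n}")
    m = X.mean(axis=1)
    s = X.std(axis=1, ddof=1)
    Cov = np.cov(X, ddof=1)
    Cov = np.atleast_2d(Cov)
    return MomentSummary(n=n, m=m, s=s, Cov=Cov)


def loo_mean(ms: MomentSummary, G_i: np.ndarray) -> np.ndarray:
    """Mean over all samples except the one with expression vector G_i."""
    G_i = np.asarray(G_i, dtype=float)
    return (ms.n * ms.m - G_i) / (ms.n - 1)


def loo_std(ms: MomentSummary, G_i: np.ndarray, m_i: np.ndarray | None = None) -> np.ndarray:
    """Leave-one-out std (ddof=1) by downdating the all-sample variance.

    Negative radicands arising from floating-point cancellation are clamped
    to 0.
    """
    if ms.n < 3:
        raise ValueError("leave-one-out std needs n >= 3")
    G_i = np.asarray(G_i, dtype=float)
    d = G_i - ms.m
    var = ((ms.n - 1) * ms.s**2 - (ms.n / (ms.n - 1)) * d**2) / (ms.n - 2)
    return np.sqrt(np.maximum(var, 0.0))


def loo_cov(ms: MomentSummary, G_i: np.ndarray, m_i: np.ndarray | None = None) -> np.ndarray:
    """Leave-one-out covariance (ddof=1) by a rank-one downdate of Cov."""
    if ms.n < 3:
        raise ValueError("leave-one-out covariance needs n >= 3")
    G_i = np.asarray(G_i, dtype=float)
    d = G_i - ms.m
    return ((ms.n - 1) * ms.Cov - (ms.n / (ms.n - 1)) * np.outer(d, d)) / (ms.n - 2)


def loo_coexpression(ms: MomentSummary, G_i: np.ndarray) -> np.ndarray:
    """Sample-deprived Pearson correlation, entirely from the downdates.

    Entries involving a gene whose retained samples are constant (std 0)
    are set to 0, with the diagonal forced to 1.
    """
    s_i = loo_std(ms, G_i)
    Cov_i = loo_cov(ms, G_i)
    with np.errstate(divide="ignore", invalid="ignore"):
        C = Cov_i / np.outer(s_i, s_i)
    ok = s_i > 0
    C[~ok, :] = 0.0
    C[:, ~ok] = 0.0
    np.fill_diagonal(C, 1.0)
    return C


def direct_loo_coexpression(expr, i: int) -> np.ndarray:
    """The oracle: drop sample i and recompute Pearson correlation fully."""
    X = _values(expr)
    n = X.shape[1]
    if n < 3:
        raise ValueError("leave-one-out co-expression needs n >= 3")
    if not 0 <= i < n:
        raise IndexError(f"sample index {i} out of range for {n} samples")
    return _pearson_rows(np.delete(X, i, axis=1))
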