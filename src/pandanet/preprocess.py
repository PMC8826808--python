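"""Assembly and normalization of the three network priors.

PANDA integrates three data sources: a TF-by-gene motif prior (W0), a
TF-by-TF cooperativity prior from protein-protein interactions (P0), and a
gene-by-gene co-expression matrix (C0, pairwise Pearson correlation of
expression profiles).  Before message passing the three matrices must share
a common TF/gene index and be brought onto a common scale by z-score
standardization across both rows and columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "RegulatoryPrior",
    "CooperativityPrior",
    "ExpressionMatrix",
    "NetworkTriple",
    "assemble_priors",
    "normalize_network",
    "compute_coexpression_prior",
    "build_network_triple",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for x in ids:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise ValueError(f"duplicate {what} identifiers: {sorted(set(dups))[:10]}")


def _check_finite(values: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))
        raise ValueError(
            f"{what} contains non-finite values at coordinates "
            f"{[tuple(int(v) for v in b) for b in bad[:10]]}"
        )


@dataclass
class RegulatoryPrior:
    """TF-by-gene prior adjacency (W0), typically 0/1 motif evidence."""

    tf_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.tf_ids), len(self.gene_ids)):
            raise ValueError(
                f"regulatory prior shape {self.values.shape} does not match "
                f"{len(self.tf_ids)} TFs x {len(self.gene_ids)} genes"
            )
        _check_unique(self.tf_ids, "TF")
        _check_unique(self.gene_ids, "gene")
        _check_finite(self.values, "regulatory prior")


@dataclass
class CooperativityPrior:
    """TF-by-TF cooperativity prior (P0) seeded from PPI evidence."""

    tf_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.tf_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"cooperativity prior must be {n}x{n}, got {self.values.shape}")
        _check_unique(self.tf_ids, "TF")
        _check_finite(self.values, "cooperativity prior")
        if n and np.max(np.abs(self.values - self.values.T)) > 1e-12:
            raise ValueError("cooperativity prior must be symmetric")


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"expression shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        _check_finite(self.values, "expression matrix")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class NetworkTriple:
    """The normalized W (TF x gene), P (TF x TF) and C (gene x gene) matrices."""

    W: np.ndarray
    P: np.ndarray
    C: np.ndarray
    tf_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        nt, ng = self.W.shape
        if self.P.shape != (nt, nt):
            raise ValueError(f"P shape {self.P.shape} incompatible with W shape {self.W.shape}")
        if self.C.shape != (ng, ng):
            raise ValueError(f"C shape {self.C.shape} incompatible with W shape {self.W.shape}")
        for name, m in (("W", self.W), ("P", self.P), ("C", self.C)):
            _check_finite(m, name)

    @property
    def n_tfs(self) -> int:
        return self.W.shape[0]

    @property
    def n_genes(self) -> int:
        return self.W.shape[1]


def _edges_to_frame(edges: Iterable, what: str) -> list[tuple[str, str, float]]:
    out = []
    for e in edges:
        if len(e) != 3:
            raise ValueError(f"{what} edge list rows must have 3 columns, got {e!r}")
        a, b, w = e
        out.append((str(a), str(b), float(w)))
    if not out:
        raise ValueError(f"{what} edge list is empty")
    return out


def assemble_priors(
    motif: Iterable,
    ppi: Iterable,
    expression: ExpressionMatrix,
    mode: str = "intersection",
) -> tuple[RegulatoryPrior, CooperativityPrior, ExpressionMatrix]:
    """Place motif, PPI and expression data onto a shared TF/gene index.

    The TF index combines the motif's TFs with the PPI's TFs; the gene index
    combines the motif's genes with the expression matrix's genes — by set
    intersection or union according to ``mode``.  Identifiers are sorted
    lexicographically so outputs are byte-stable.  In union mode, evidence
    absent from a source is filled neutrally: motif entries 0, PPI
    off-diagonal 0, and genes missing from the expression matrix receive
    constant-zero expression rows.  The PPI diagonal is always set to 1
    (every TF trivially cooperates with itself).

    Parameters
    ----------
    motif : iterable of (tf, gene, weight)
    ppi : iterable of (tf, tf, weight)
    expression : ExpressionMatrix
    mode : {"intersection", "union"}
    """
    if mode not in ("intersection", "union"):
        raise ValueError(f"mode must be 'intersection' or 'union', got {mode!r}")
    motif_edges = _edges_to_frame(motif, "motif")
    ppi_edges = _edges_to_frame(ppi, "PPI")

    if len({(t, g) for t, g, _ in motif_edges}) != len(motif_edges):
        raise ValueError("motif edge list contains duplicate (TF, gene) pairs")
    if len({frozenset((a, b)) if a != b else (a,) for a, b, _ in ppi_edges}) != len(ppi_edges):
        raise ValueError("PPI edge list contains duplicate TF pairs")

    motif_tfs = {t for t, _, _ in motif_edges}
    motif_genes = {g for _, g, _ in motif_edges}
    ppi_tfs = {a for a, b, _ in ppi_edges} | {b for a, b, _ in ppi_edges}
    expr_genes = set(expression.gene_ids)

    if mode == "intersection":
        tf_index = sorted(motif_tfs & ppi_tfs)
        gene_index = sorted(motif_genes & expr_genes)
        if not tf_index:
            raise ValueError("motif prior and PPI prior share no TFs (empty intersection)")
        if not gene_index:
            raise ValueError(
                "motif prior and expression matrix share no genes (empty intersection)"
            )
    else:
        tf_index = sorted(motif_tfs | ppi_tfs)
        gene_index = sorted(motif_genes | expr_genes)

    tf_pos = {t: i for i, t in enumerate(tf_index)}
    gene_pos = {g: i for i, g in enumerate(gene_index)}

    W0 = np.zeros((len(tf_index), len(gene_index)))
    for t, g, w in motif_edges:
        if t in tf_pos and g in gene_pos:
            W0[tf_pos[t], gene_pos[g]] = w

    P0 = np.zeros((len(tf_index), len(tf_index)))
    for a, b, w in ppi_edges:
        if a in tf_pos and b in tf_pos:
            P0[tf_pos[a], tf_pos[b]] = w
            P0[tf_pos[b], tf_pos[a]] = w
    np.fill_diagonal(P0, 1.0)

    expr_pos = {g: i for i, g in enumerate(expression.gene_ids)}
    E = np.zeros((len(gene_index), expression.n_samples))
    for g, i in gene_pos.items():
        if g in expr_pos:
            E[i] = expression.values[expr_pos[g]]

    return (
        RegulatoryPrior(tf_index, gene_index, W0),
        CooperativityPrior(tf_index, P0),
        ExpressionMatrix(gene_index, list(expression.sample_ids), E),
    )


def normalize_network(M: np.ndarray) -> np.ndarray:
    """Z-score standardize a matrix across both rows and columns.

    Each entry receives ``(zrow + zcol) / sqrt(2)`` where ``zrow``
    standardizes within its row and ``zcol`` within its column (both with
    ddof=1).  The 1/sqrt(2) keeps the sum of two unit-variance terms at unit
    variance.  Entries whose row (or column) is constant fall back to the
    other dimension's z-score alone, still divided by sqrt(2); entries
    degenerate in both dimensions become 0.  The result is always finite.
    """
    M = np.asarray(M, dtype=float)
    _check_finite(M, "normalize_network input")
    if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError(f"normalize_network needs a matrix of at least 2x2, got {M.shape}")

    row_mean = M.mean(axis=1, keepdims=True)
    row_std = M.std(axis=1, ddof=1, keepdims=True)
    col_mean = M.mean(axis=0, keepdims=True)
    col_std = M.std(axis=0, ddof=1, keepdims=True)

    with np.errstate(divide="ignore", invalid="ignore"):
        zrow = (M - row_mean) / row_std
        zcol = (M - col_mean) / col_std

    row_ok = np.broadcast_to(row_std > 0, M.shape)
    col_ok = np.broadcast_to(col_std > 0, M.shape)
    zrow = np.where(row_ok, zrow, 0.0)
    zcol = np.where(col_ok, zcol, 0.0)

    out = (zrow + zcol) / math.sqrt(2.0)
    # degenerate in both dimensions -> exactly 0 (0 + 0 above already)
    return out


def compute_coexpression_prior(expr: ExpressionMatrix | np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation between gene expression profiles (C0).

    Genes with constant expression have undefined correlations; those
    entries are set to 0 off the diagonal and 1 on it.
    """
    X = expr.values if isinstance(expr, ExpressionMatrix) else np.asarray(expr, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("co-expression requires at least 2 samples")
    return _pearson_rows(X)


def _pearson_rows(X: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation with zero-variance guard."""
    n = X.shape[1]
    Xc = X - X.mean(axis=1, keepdims=True)
    s = X.std(axis=1, ddof=1)
    cov = (Xc @ Xc.T) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        C = cov / np.outer(s, s)
    ok = s > 0
    C[~ok, :] = 0.0
    C[:, ~ok] = 0.0
    np.fill_diagonal(C, 1.0)
    return C


def build_network_triple(
    motif_prior: RegulatoryPrior,
    coop_prior: CooperativityPrior,
    expression: ExpressionMatrix,
) -> NetworkTriple:
    """Normalize the three aligned inputs into the message-passing triple.

    The co-expression matrix is computed from the expression values, then
    all three matrices are z-score standardized with :func:`normalize_network`.
    """
    if motif_prior.tf_ids != coop_prior.tf_ids:
        raise ValueError("motif and cooperativity priors are not on the same TF index")
    if motif_prior.gene_ids != expression.gene_ids:
        raise ValueError("motif prior and expression are not on the same gene index")
    C0 = compute_coexpression_prior(expression)
    return NetworkTriple(
        W=normalize_network(motif_prior.values),
        P=symmetrize(normalize_network(coop_prior.values)),
        C=symmetrize(normalize_network(C0)),
        tf_ids=list(motif_prior.tf_ids),
        gene_ids=list(motif_prior.gene_ids),
    )


def symmetrize(M: np.ndarray) -> np.ndarray:
    """Restore exact symmetry lost to floating-point reduction order.

    Row-wise and column-wise z-scores of a symmetric matrix are equal in
    exact arithmetic but differ in the last bits; averaging with the
    transpose makes P and C exactly symmetric so half-storage is lossless.
    """
    return (M + M.T) / 2.0
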