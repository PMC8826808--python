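"""PANDA message passing and its PUMA and SPIDER variants.

PANDA refines a TF-by-gene regulatory network W to be maximally consistent
with TF-TF cooperativity evidence P and gene-gene co-expression evidence C.
Each iteration computes two TF-by-gene messages:

* Responsibility R — similarity between each TF's cooperativity profile
  (row of P) and each gene's regulator profile (column of W);
* Availability A — similarity between each TF's target profile (row of W)
  and each gene's co-expression profile (column of C),

and moves W a step of size alpha toward their average, ``W <- (1-alpha) W +
alpha (R+A)/2``.  P and C are then updated toward the pairwise similarity of
the new W's TF rows and gene columns respectively, with their diagonals
handled separately (self-similarity carries no evidence).  The loop stops
when the mean absolute gap between W and its proposed update — the
"hamming" statistic — falls below the tolerance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .backend import (
    BackendHandle,
    ReferenceBackend,
    config_digest,
    get_backend,
    restore_checkpoint,
    save_checkpoint,
    stage_inputs,
)
from .preprocess import (
    CooperativityPrior,
    ExpressionMatrix,
    NetworkTriple,
    RegulatoryPrior,
    build_network_triple,
)
from .similarity import METRICS

__all__ = [
    "PandaConfig",
    "PandaState",
    "RegulatoryNetwork",
    "ConvergenceWarning",
    "NumericalError",
    "update_diagonal",
    "panda_step",
    "run_panda",
    "run_puma",
    "run_spider",
]


class ConvergenceWarning(UserWarning):
    """The iteration cap was reached before the tolerance was met."""


# Negated distances that scale linearly with their inputs.  Fed raw into the
# update they admit no fixed point: the diagonal refresh grows the state
# scale every iteration and a degree-1 homogeneous message grows with it, so
# the gap between W and its proposed update diverges instead of closing.
# For these metrics the messages are standardized before entering the
# update — Responsibility within each TF row, Availability within each gene
# column (the two directions in which the growing P and C diagonals inject
# offsets) — which makes the iteration scale-free and restores a fixed
# point.  The P/C state is additionally rescaled once its magnitude would
# start costing double-precision digits inside the metric's accumulation
# (squares/sums saturate sooner than max/sqrt forms, hence the lower cap).
_SCALE_HOMOGENEOUS = {"euclidean", "squared_euclidean", "cityblock", "chebychev"}
_STATE_CAP = {"euclidean": 1e12, "chebychev": 1e12,
              "squared_euclidean": 1e6, "cityblock": 1e6}


def _zrows(S: np.ndarray) -> np.ndarray:
    m = S.mean(axis=1, keepdims=True)
    s = S.std(axis=1, ddof=1, keepdims=True)
    return np.where(s > 0, (S - m) / np.where(s > 0, s, 1.0), np.zeros((), dtype=S.dtype))


class NumericalError(RuntimeError):
    """A non-finite value appeared during message passing."""


@dataclass(frozen=True)
class PandaConfig:
    """Settings for one message-passing run.

    Parameters
    ----------
    alpha : float
        Learning rate in (0, 1]; the step size of each update.  0.1 is the
        conventional default in this method family.
    metric : str
        Similarity metric; one of :data:`pandanet.similarity.METRICS`.
    tolerance : float
        Convergence threshold on the hamming statistic (mean absolute gap
        between W and its proposed update).
    max_iter : int
        Iteration cap; reaching it without convergence is a warning, not an
        error — partial networks are still inspectable.
    precision : {"double", "single"}
        Floating-point width for all run arithmetic.
    backend : BackendHandle
        Compute backend selector.
    """

    alpha: float = 0.1
    metric: str = "tfunction"
    tolerance: float = 1e-3
    max_iter: int = 200
    precision: str = "double"
    backend: BackendHandle = field(default_factory=BackendHandle)

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if str(self.metric).lower() not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; valid: {', '.join(METRICS)}")
        if self.precision not in ("single", "double"):
            raise ValueError(f"precision must be 'single' or 'double', got {self.precision!r}")
        if self.backend.precision != self.precision:
            object.__setattr__(self, "backend", replace(self.backend, precision=self.precision))


@dataclass
class PandaState:
    """The mutable loop state: current matrices, messages, and progress."""

    W: np.ndarray
    P: np.ndarray
    C: np.ndarray
    R: Optional[np.ndarray] = None
    A: Optional[np.ndarray] = None
    iteration: int = 0
    hamming: float = math.inf


@dataclass
class RegulatoryNetwork:
    """The fitted regulatory network W_f and its convergence record."""

    tf_ids: list[str]
    gene_ids: list[str]
    weights: np.ndarray
    iterations_used: int
    converged: bool
    hamming_trace: list[float] = field(default_factory=list)


def _require_finite(M: np.ndarray, stage: str) -> None:
    if not np.all(np.isfinite(M)):
        raise NumericalError(f"non-finite values produced at stage {stage}")


def update_diagonal(M: np.ndarray, alpha: float, k: int) -> np.ndarray:
    """Replace the diagonal of a square similarity matrix.

    Each diagonal entry becomes ``dim(M) * std * exp(2*alpha*k)`` where
    ``std`` is the population standard deviation (ddof=0) of that row's
    off-diagonal entries.  The growing exponential makes P and C
    progressively diagonal-dominant, which anchors each TF and gene to its
    own profile and drives the message-passing fixed point.
    """
    M = np.asarray(M)
    n = M.shape[0]
    if M.ndim != 2 or M.shape[1] != n:
        raise ValueError("update_diagonal requires a square matrix")
    out = M.copy()
    if n < 2:
        out[np.diag_indices(n)] = 0.0
        return out
    D = M.copy()
    idx = np.diag_indices(n)
    D[idx] = 0.0
    m = D.sum(axis=1) / (n - 1)
    # off-diagonal deviations; the diagonal slot contributes (0 - m)^2 which
    # is removed again below
    sq = ((D - m[:, None]) ** 2).sum(axis=1) - m**2
    var = np.maximum(sq / (n - 1), 0.0)
    out[idx] = n * np.sqrt(var) * math.exp(2.0 * float(alpha) * int(k))
    return out


def _messages(W, P, C, metric: str, backend: ReferenceBackend):
    """Responsibility (P rows vs W gene columns) and Availability (W rows
    vs C gene columns), both TF-by-gene.

    Scale-homogeneous distance messages are standardized (R within TF
    rows, A within gene columns) so the update has a fixed point; see
    :data:`_SCALE_HOMOGENEOUS`.
    """
    R = backend.pairwise(P, W.T, metric)
    A = backend.pairwise(W, C.T, metric)
    if metric in _SCALE_HOMOGENEOUS:
        R = _zrows(R)
        A = _zrows(A.T).T
    _require_finite(R, "R")
    _require_finite(A, "A")
    return R, A


def _commit(W, P, C, update, alpha: float, k: int, metric: str,
            backend: ReferenceBackend, frozen: Optional[np.ndarray] = None,
            P_prior: Optional[np.ndarray] = None):
    """Apply one accepted update to W, then refresh P and C toward the
    pairwise self-similarity of the new W."""
    W_next = (1.0 - alpha) * W + alpha * update
    _require_finite(W_next, "W")

    P_upd = update_diagonal(backend.pairwise(W_next, W_next, metric), alpha, k)
    P_next = (1.0 - alpha) * P + alpha * P_upd

    Wt = W_next.T
    C_upd = update_diagonal(backend.pairwise(Wt, Wt, metric), alpha, k)
    C_next = (1.0 - alpha) * C + alpha * C_upd

    cap = _STATE_CAP.get(metric)
    if cap is not None:
        mP = float(np.abs(P_next).max())
        if mP > cap:
            P_next = P_next * (cap / mP)
        mC = float(np.abs(C_next).max())
        if mC > cap:
            C_next = C_next * (cap / mC)

    if frozen is not None and frozen.size:
        P_next[frozen, :] = P_prior[frozen, :]
        P_next[:, frozen] = P_prior[:, frozen]
    _require_finite(P_next, "P")
    _require_finite(C_next, "C")
    return W_next, P_next, C_next


def panda_step(state: PandaState, cfg: PandaConfig,
               backend: Optional[ReferenceBackend] = None) -> PandaState:
    """One full message-passing update.

    The hamming statistic is measured between the pre-update W and the
    proposed update (R+A)/2, then the update is committed.  With alpha=1
    the new W equals (R+A)/2 exactly.
    """
    backend = backend or get_backend(cfg.backend)
    metric = str(cfg.metric).lower()
    R, A = _messages(state.W, state.P, state.C, metric, backend)
    update = (R + A) / 2.0
    hamming = float(np.mean(np.abs(state.W - update)))
    W, P, C = _commit(state.W, state.P, state.C, update, cfg.alpha,
                      state.iteration, metric, backend)
    return PandaState(W=W, P=P, C=C, R=R, A=A,
                      iteration=state.iteration + 1, hamming=hamming)


def run_panda(
    triple: NetworkTriple,
    cfg: PandaConfig = PandaConfig(),
    *,
    mirna_regulators: Optional[Sequence[str]] = None,
    resume_from: Optional[str] = None,
    checkpoint_every: int = 10,
    stop_after: Optional[int] = None,
) -> RegulatoryNetwork:
    """Iterate message passing to convergence on a normalized triple.

    The loop checks convergence before committing each update: if the mean
    absolute gap between the current W and its proposed update is already
    below the tolerance, W is returned unchanged.  The result is a pure
    function of ``(triple, cfg)``; backends and batching only affect it
    within precision-mode tolerance.

    Parameters
    ----------
    triple : NetworkTriple
        Normalized W/P/C (see :func:`pandanet.preprocess.build_network_triple`).
    cfg : PandaConfig
    mirna_regulators : sequence of str, optional
        TF identifiers whose cooperativity rows/columns are pinned to their
        normalized prior after every P update (the PUMA variant).
    resume_from : str, optional
        Path to a checkpoint written by an earlier, interrupted run with the
        same configuration and inputs.
    checkpoint_every : int
        Snapshot frequency (iterations) when the backend handle carries a
        ``checkpoint_path``.
    stop_after : int, optional
        Interrupt the run after this many committed iterations (used to
        exercise checkpoint/restart); the partial state is checkpointed.
    """
    handle = cfg.backend
    backend = get_backend(handle)
    metric = str(cfg.metric).lower()
    staged = stage_inputs(triple, handle, backend)
    W, P, C = staged.W, staged.P, staged.C

    frozen = None
    P_prior = None
    if mirna_regulators is not None:
        pos = {t: i for i, t in enumerate(triple.tf_ids)}
        unknown = [t for t in mirna_regulators if t not in pos]
        if unknown:
            raise ValueError(f"unknown regulator identifiers: {unknown}")
        frozen = np.array(sorted(pos[t] for t in set(mirna_regulators)), dtype=int)
        P_prior = P.copy()

    digest = config_digest(cfg, triple)
    k = 0
    if resume_from is not None:
        cp = restore_checkpoint(resume_from, digest)
        W, P, C, k = cp.W, cp.P, cp.C, cp.iteration

    trace: list[float] = []
    converged = False
    while True:
        R, A = _messages(W, P, C, metric, backend)
        update = (R + A) / 2.0
        hamming = float(np.mean(np.abs(W - update)))
        trace.append(hamming)
        if hamming < cfg.tolerance:
            converged = True
            break
        if k >= cfg.max_iter:
            break
        W, P, C = _commit(W, P, C, update, cfg.alpha, k, metric, backend,
                          frozen=frozen, P_prior=P_prior)
        k += 1
        state = PandaState(W=W, P=P, C=C, iteration=k, hamming=hamming)
        if handle.checkpoint_path and (k % checkpoint_every == 0):
            save_checkpoint(state, handle, digest)
        if stop_after is not None and k >= stop_after:
            if handle.checkpoint_path:
                save_checkpoint(state, handle, digest)
            return RegulatoryNetwork(
                tf_ids=list(triple.tf_ids), gene_ids=list(triple.gene_ids),
                weights=backend.fetch(W), iterations_used=k, converged=False,
                hamming_trace=trace,
            )

    if not converged:
        warnings.warn(
            f"PANDA did not converge in {cfg.max_iter} iterations "
            f"(hamming={trace[-1]:.3e}, tolerance={cfg.tolerance:.3e})",
            ConvergenceWarning,
            stacklevel=2,
        )
    return RegulatoryNetwork(
        tf_ids=list(triple.tf_ids),
        gene_ids=list(triple.gene_ids),
        weights=backend.fetch(W),
        iterations_used=k,
        converged=converged,
        hamming_trace=trace,
    )


def run_puma(
    triple: NetworkTriple,
    mirna_regulators: Sequence[str],
    cfg: PandaConfig = PandaConfig(),
    **kwargs,
) -> RegulatoryNetwork:
    """PANDA seeded with miRNA regulators whose cooperativity is pinned.

    miRNAs repress targets post-transcriptionally and do not form the
    protein complexes the P update models, so their rows and columns of P
    are reset to the normalized prior after every update.  With an empty
    regulator set this reduces exactly to :func:`run_panda`.
    """
    return run_panda(triple, cfg, mirna_regulators=list(mirna_regulators), **kwargs)


def run_spider(
    motif_prior: RegulatoryPrior,
    coop_prior: CooperativityPrior,
    expression: ExpressionMatrix,
    chromatin_mask: np.ndarray,
    cfg: PandaConfig = PandaConfig(),
    **kwargs,
) -> RegulatoryNetwork:
    """PANDA with the motif prior masked by open-chromatin evidence.

    The 0/1 mask zeroes motif edges where closed chromatin makes binding
    unlikely, *before* normalization; message passing then proceeds
    unchanged.  An all-ones mask reduces exactly to PANDA on the same
    inputs.
    """
    mask = np.asarray(chromatin_mask)
    if mask.shape != motif_prior.values.shape:
        raise ValueError(
            f"chromatin mask shape {mask.shape} does not match the motif prior "
            f"shape {motif_prior.values.shape}"
        )
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("chromatin mask values must be 0 or 1")
    masked = RegulatoryPrior(
        list(motif_prior.tf_ids), list(motif_prior.gene_ids),
        motif_prior.values * mask,
    )
    triple = build_network_triple(masked, coop_prior, expression)
    return run_panda(triple, cfg, **kwargs)
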