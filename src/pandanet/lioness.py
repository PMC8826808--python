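"""LIONESS: one regulatory network per sample by leave-one-out interpolation.

An aggregate PANDA network W_all pools evidence from all n samples; a
second network W_minus_i pools all samples but i.  The network attributed
to sample i alone is the linear extrapolation

    W_sample_i = n (W_all - W_minus_i) + W_minus_i.

Only the co-expression matrix changes between the per-sample runs — the
motif and PPI priors are condition-independent and are normalized once.
Samples are independent, so the per-sample runs can be batched across
workers; the batching is a pure scheduling concern and never changes the
result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .coexpression import direct_loo_coexpression, init_moments, loo_coexpression
from .panda import PandaConfig, RegulatoryNetwork, run_panda
from .preprocess import (
    CooperativityPrior,
    ExpressionMatrix,
    NetworkTriple,
    RegulatoryPrior,
    compute_coexpression_prior,
    normalize_network,
    symmetrize,
)

__all__ = ["BatchPlan", "SampleNetworkSet", "sample_network", "schedule_batches", "run_lioness"]


@dataclass(frozen=True)
class BatchPlan:
    """Deterministic round-robin assignment of samples to workers.

    Sample indices are 1-based, matching this tool family's interfaces;
    sample j in [start, end] goes to worker (j - start) mod worker_count.
    """

    n_samples: int
    worker_count: int = 1
    start: int = 1
    end: Optional[int] = None

    def __post_init__(self) -> None:
        end = self.end if self.end is not None else self.n_samples
        object.__setattr__(self, "end", end)
        if self.worker_count < 1:
            raise ValueError("worker_count must be >= 1")
        if not (1 <= self.start <= end <= self.n_samples):
            raise ValueError(
                f"invalid sample range [{self.start}, {end}] for {self.n_samples} samples"
            )

    @property
    def assignment(self) -> dict[int, int]:
        return {j: (j - self.start) % self.worker_count for j in range(self.start, self.end + 1)}

    def for_worker(self, w: int) -> list[int]:
        return [j for j, wid in self.assignment.items() if wid == w]


def schedule_batches(n_samples: int, worker_count: int, start: int = 1,
                     end: Optional[int] = None) -> BatchPlan:
    """Build the round-robin batch plan for a (sub)range of samples."""
    return BatchPlan(n_samples=n_samples, worker_count=worker_count, start=start, end=end)


def sample_network(W_all: np.ndarray, W_minus_i: np.ndarray, n: int) -> np.ndarray:
    """LIONESS linear interpolation for one sample.

    ``n (W_all - W_minus_i) + W_minus_i`` — the edge weight sample i must
    contribute for the population average to come out at W_all.
    """
    W_all = np.asarray(W_all)
    W_minus_i = np.asarray(W_minus_i)
    if W_all.shape != W_minus_i.shape:
        raise ValueError(
            f"shape mismatch: aggregate {W_all.shape} vs sample-deprived {W_minus_i.shape}"
        )
    if n < 2:
        raise ValueError("sample_network needs n >= 2")
    return n * (W_all - W_minus_i) + W_minus_i


@dataclass
class SampleNetworkSet:
    """All single-sample networks of a run, plus the aggregate and manifest."""

    sample_ids: list[str]
    networks: dict[str, np.ndarray]
    aggregate: RegulatoryNetwork
    config: PandaConfig
    per_sample: dict[str, dict] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)


def _worker_task(indices: list[int], X: np.ndarray, moments, Wn: np.ndarray,
                 Pn: np.ndarray, tf_ids, gene_ids, cfg: PandaConfig,
                 online: bool, n: int, W_all: np.ndarray):
    """Compute the networks for one worker's sample indices.

    Inbound data is the shared read-only inputs plus the index list;
    outbound data is one result matrix (and a convergence record) per
    index — the only exchange a non-shared-memory worker would need.
    """
    out = {}
    for j in indices:  # 1-based
        i = j - 1
        try:
            if online:
                C_i = loo_coexpression(moments, X[:, i])
            else:
                C_i = direct_loo_coexpression(X, i)
            triple_i = NetworkTriple(W=Wn, P=Pn, C=symmetrize(normalize_network(C_i)),
                                     tf_ids=tf_ids, gene_ids=gene_ids)
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                net_i = run_panda(triple_i, cfg)
            W_i = sample_network(W_all, net_i.weights, n)
            out[j] = ("ok", W_i, net_i.converged, net_i.iterations_used)
        except Exception as exc:  # isolate per-sample failures
            out[j] = ("failed", str(exc), False, 0)
    return out


def run_lioness(
    expression: ExpressionMatrix,
    motif_prior: RegulatoryPrior,
    coop_prior: CooperativityPrior,
    cfg: PandaConfig = PandaConfig(),
    online: bool = True,
    plan: Optional[BatchPlan] = None,
) -> SampleNetworkSet:
    """Estimate one network per sample around the aggregate PANDA network.

    The motif and PPI priors are normalized once and reused for every
    per-sample run; only the co-expression matrix is recomputed (on-line by
    rank-one downdates when ``online`` is true, otherwise by direct
    recomputation) and renormalized.  A failing sample is recorded in the
    failure manifest and the run continues.

    The result is identical for any worker count and any consecutive
    splitting of the sample range.
    """
    X = expression.values
    n = expression.n_samples
    if n < 3:
        raise ValueError(f"LIONESS needs at least 3 samples, got {n}")
    if plan is None:
        plan = schedule_batches(n, 1)
    if plan.n_samples != n:
        raise ValueError("batch plan was built for a different sample count")

    Wn = normalize_network(motif_prior.values)
    Pn = symmetrize(normalize_network(coop_prior.values))
    C0 = compute_coexpression_prior(expression)
    triple = NetworkTriple(W=Wn, P=Pn, C=symmetrize(normalize_network(C0)),
                           tf_ids=list(motif_prior.tf_ids),
                           gene_ids=list(motif_prior.gene_ids))
    aggregate = run_panda(triple, cfg)

    moments = init_moments(expression) if online else None

    results: dict[int, tuple] = {}
    for w in range(plan.worker_count):
        indices = plan.for_worker(w)
        if indices:
            results.update(
                _worker_task(indices, X, moments, Wn, Pn, triple.tf_ids,
                             triple.gene_ids, cfg, online, n, aggregate.weights)
            )

    networks: dict[str, np.ndarray] = {}
    per_sample: dict[str, dict] = {}
    failures: dict[str, str] = {}
    processed_ids = []
    for j in sorted(results):
        sid = expression.sample_ids[j - 1]
        processed_ids.append(sid)
        status, payload, converged, iters = results[j]
        if status == "ok":
            networks[sid] = payload
            per_sample[sid] = {"converged": converged, "iterations": iters}
        else:
            failures[sid] = payload
    return SampleNetworkSet(
        sample_ids=processed_ids,
        networks=networks,
        aggregate=aggregate,
        config=cfg,
        per_sample=per_sample,
        failures=failures,
    )
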