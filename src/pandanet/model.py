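"""Model/results objects: the package's high-level fitting interface.

Follows the convention of statistical modelling libraries: a model object
is built from data, ``fit()`` runs the estimation and returns a results
object carrying the estimates, diagnostics and a ``summary()`` table.

>>> motif, ppi, expr = gen_case("small", scale=0.03, seed=7)
>>> res = Panda(motif_edges, ppi_edges, expr, alpha=0.1).fit()
>>> res.converged, res.iterations_used
(True, 32)
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .backend import BackendHandle
from .lioness import BatchPlan, SampleNetworkSet, run_lioness, schedule_batches
from .panda import PandaConfig, RegulatoryNetwork, run_panda
from .preprocess import (
    CooperativityPrior,
    ExpressionMatrix,
    RegulatoryPrior,
    assemble_priors,
    build_network_triple,
)

__all__ = ["Panda", "Puma", "Spider", "Lioness",
           "PandaResults", "LionessResults"]


def _as_edges(obj, what: str):
    if isinstance(obj, pd.DataFrame):
        if obj.shape[1] != 3:
            raise ValueError(f"{what} frame must have 3 columns (id, id, weight)")
        return list(obj.itertuples(index=False, name=None))
    return list(obj)


def _as_expression(obj) -> ExpressionMatrix:
    if isinstance(obj, ExpressionMatrix):
        return obj
    if isinstance(obj, pd.DataFrame):
        return ExpressionMatrix(
            [str(g) for g in obj.index],
            [str(s) for s in obj.columns],
            obj.to_numpy(dtype=float),
        )
    raise TypeError("expression must be an ExpressionMatrix or a genes x samples DataFrame")


class Panda:
    """Message-passing regulatory network model.

    Parameters
    ----------
    motif : edge list or DataFrame
        (TF, gene, weight) motif prior rows.
    ppi : edge list or DataFrame
        (TF, TF, weight) cooperativity prior rows.
    expression : ExpressionMatrix or DataFrame
        Genes x samples.
    mode : {"intersection", "union"}
        How the three sources are placed on a common index.
    Remaining keyword arguments are :class:`~pandanet.panda.PandaConfig`
    fields (alpha, metric, tolerance, max_iter, precision, backend).
    """

    def __init__(self, motif, ppi, expression, mode: str = "intersection", **config):
        expr = _as_expression(expression)
        self.motif_prior, self.coop_prior, self.expression = assemble_priors(
            _as_edges(motif, "motif"), _as_edges(ppi, "PPI"), expr, mode=mode
        )
        self.mode = mode
        self.config = PandaConfig(**config)

    @classmethod
    def from_files(cls, motif_path: str, ppi_path: str, expression_path: str,
                   mode: str = "intersection", **config) -> "Panda":
        from .io import read_expression, read_prior

        return cls(read_prior(motif_path), read_prior(ppi_path),
                   read_expression(expression_path), mode=mode, **config)

    # Subclasses override to alter the prior or the run.
    def _motif_for_fit(self) -> RegulatoryPrior:
        return self.motif_prior

    def _run(self, triple, cfg, **kwargs) -> RegulatoryNetwork:
        return run_panda(triple, cfg, **kwargs)

    def fit(self, **kwargs) -> "PandaResults":
        triple = build_network_triple(self._motif_for_fit(), self.coop_prior,
                                      self.expression)
        net = self._run(triple, self.config, **kwargs)
        return PandaResults(self, net)

    @property
    def tf_ids(self) -> list[str]:
        return self.motif_prior.tf_ids

    @property
    def gene_ids(self) -> list[str]:
        return self.motif_prior.gene_ids


class Puma(Panda):
    """PANDA variant for miRNA regulators (cooperativity pinned to prior)."""

    def __init__(self, motif, ppi, expression, mirna_regulators: Sequence[str],
                 mode: str = "intersection", **config):
        super().__init__(motif, ppi, expression, mode=mode, **config)
        unknown = [m for m in mirna_regulators if m not in set(self.tf_ids)]
        if unknown:
            raise ValueError(f"unknown regulator identifiers: {unknown}")
        self.mirna_regulators = list(mirna_regulators)

    def _run(self, triple, cfg, **kwargs):
        return run_panda(triple, cfg, mirna_regulators=self.mirna_regulators, **kwargs)


class Spider(Panda):
    """PANDA variant with the motif prior masked by open chromatin."""

    def __init__(self, motif, ppi, expression, chromatin_mask: np.ndarray,
                 mode: str = "intersection", **config):
        super().__init__(motif, ppi, expression, mode=mode, **config)
        mask = np.asarray(chromatin_mask)
        if mask.shape != self.motif_prior.values.shape:
            raise ValueError(
                f"chromatin mask shape {mask.shape} does not match the assembled "
                f"motif prior {self.motif_prior.values.shape}"
            )
        if not np.isin(mask, (0, 1)).all():
            raise ValueError("chromatin mask values must be 0 or 1")
        self.chromatin_mask = mask

    def _motif_for_fit(self) -> RegulatoryPrior:
        return RegulatoryPrior(
            list(self.motif_prior.tf_ids), list(self.motif_prior.gene_ids),
            self.motif_prior.values * self.chromatin_mask,
        )


class PandaResults:
    """A fitted regulatory network with its convergence diagnostics."""

    def __init__(self, model: Panda, network: RegulatoryNetwork):
        self.model = model
        self.network = network

    @property
    def weights(self) -> np.ndarray:
        return self.network.weights

    @property
    def tf_ids(self) -> list[str]:
        return self.network.tf_ids

    @property
    def gene_ids(self) -> list[str]:
        return self.network.gene_ids

    @property
    def converged(self) -> bool:
        return self.network.converged

    @property
    def iterations_used(self) -> int:
        return self.network.iterations_used

    @property
    def hamming_trace(self) -> list[float]:
        return self.network.hamming_trace

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.tf_ids, columns=self.gene_ids)

    def to_edgelist(self) -> pd.DataFrame:
        prior = self.model.motif_prior.values
        tf = np.repeat(self.tf_ids, len(self.gene_ids))
        gene = np.tile(self.gene_ids, len(self.tf_ids))
        return pd.DataFrame({
            "tf": tf, "gene": gene,
            "prior": prior.ravel(), "weight": self.weights.ravel(),
        })

    def save(self, path: str, format: str = "edge_tsv") -> None:
        from .io import write_network

        write_network(self.network, path, format=format,
                      prior=self.model.motif_prior.values)

    def summary(self) -> str:
        cfg = self.model.config
        w = self.weights
        lines = [
            "      PANDA regulatory network results",
            "=" * 46,
            f"TFs                 {len(self.tf_ids):>10d}",
            f"Genes               {len(self.gene_ids):>10d}",
            f"Samples             {self.model.expression.n_samples:>10d}",
            f"Metric              {cfg.metric:>10s}",
            f"Learning rate       {cfg.alpha:>10.3f}",
            f"Precision           {cfg.precision:>10s}",
            f"Converged           {str(self.converged):>10s}",
            f"Iterations          {self.iterations_used:>10d}",
            f"Final hamming       {self.hamming_trace[-1]:>10.3e}"
            if self.hamming_trace else "Final hamming              n/a",
            f"Edge weight mean    {float(w.mean()):>10.4f}",
            f"Edge weight std     {float(w.std()):>10.4f}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def plot_convergence(self, ax=None):
        """Semilog plot of the hamming statistic per iteration."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.semilogy(range(len(self.hamming_trace)), self.hamming_trace, marker="o")
        ax.axhline(self.model.config.tolerance, ls="--", color="grey")
        ax.set_xlabel("iteration")
        ax.set_ylabel("mean |W - (R+A)/2|")
        ax.set_title("message-passing convergence")
        return ax


class Lioness:
    """Single-sample network model around an aggregate PANDA fit.

    ``fit()`` estimates one TF x gene network per sample by leave-one-out
    linear interpolation, recomputing only the co-expression matrix per
    sample (on-line rank-one downdates by default).
    """

    def __init__(self, motif, ppi, expression, mode: str = "intersection",
                 online: bool = True, workers: int = 1,
                 start: int = 1, end: Optional[int] = None, **config):
        expr = _as_expression(expression)
        self.motif_prior, self.coop_prior, self.expression = assemble_priors(
            _as_edges(motif, "motif"), _as_edges(ppi, "PPI"), expr, mode=mode
        )
        self.online = online
        self.config = PandaConfig(**config)
        self.plan = schedule_batches(self.expression.n_samples, workers, start, end)

    @classmethod
    def from_files(cls, motif_path: str, ppi_path: str, expression_path: str,
                   **kwargs) -> "Lioness":
        from .io import read_expression, read_prior

        return cls(read_prior(motif_path), read_prior(ppi_path),
                   read_expression(expression_path), **kwargs)

    def fit(self) -> "LionessResults":
        nets = run_lioness(self.expression, self.motif_prior, self.coop_prior,
                           self.config, online=self.online, plan=self.plan)
        return LionessResults(self, nets)


class LionessResults:
    """The collection of single-sample networks from one LIONESS run."""

    def __init__(self, model: Lioness, result: SampleNetworkSet):
        self.model = model
        self.result = result

    @property
    def sample_ids(self) -> list[str]:
        return self.result.sample_ids

    @property
    def networks(self) -> dict[str, np.ndarray]:
        return self.result.networks

    @property
    def aggregate(self) -> RegulatoryNetwork:
        return self.result.aggregate

    @property
    def failures(self) -> dict[str, str]:
        return self.result.failures

    def network_frame(self, sample_id: str) -> pd.DataFrame:
        return pd.DataFrame(self.networks[sample_id],
                            index=self.aggregate.tf_ids,
                            columns=self.aggregate.gene_ids)

    def manifest(self) -> pd.DataFrame:
        rows = []
        for sid in self.sample_ids:
            if sid in self.networks:
                rec = self.result.per_sample[sid]
                rows.append({"sample": sid, "status": "ok",
                             "converged": rec["converged"],
                             "iterations": rec["iterations"]})
            else:
                rows.append({"sample": sid, "status": "failed",
                             "converged": False, "iterations": 0})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        man = self.manifest()
        n_ok = int((man["status"] == "ok").sum())
        lines = [
            "      LIONESS single-sample network results",
            "=" * 50,
            f"Samples processed     {len(man):>8d}",
            f"Succeeded             {n_ok:>8d}",
            f"Failed                {len(man) - n_ok:>8d}",
            f"Aggregate converged   {str(self.aggregate.converged):>8s}",
            f"Aggregate iterations  {self.aggregate.iterations_used:>8d}",
            f"On-line co-expression {str(self.model.online):>8s}",
            f"Workers               {self.model.plan.worker_count:>8d}",
            "=" * 50,
        ]
        return "\n".join(lines)

    def save(self, out_dir: str, format: str = "edge_tsv") -> pd.DataFrame:
        """One file per sample plus a manifest TSV; returns the manifest."""
        import os

        from .io import write_network

        os.makedirs(out_dir, exist_ok=True)
        ext = "tsv" if format == "edge_tsv" else "h5"
        man = self.manifest()
        paths = []
        for sid in man["sample"]:
            if sid in self.networks:
                net = RegulatoryNetwork(
                    tf_ids=self.aggregate.tf_ids, gene_ids=self.aggregate.gene_ids,
                    weights=self.networks[sid],
                    iterations_used=self.result.per_sample[sid]["iterations"],
                    converged=self.result.per_sample[sid]["converged"],
                )
                p = os.path.join(out_dir, f"{sid}.{ext}")
                write_network(net, p, format=format,
                              prior=self.model.motif_prior.values)
                paths.append(p)
            else:
                paths.append("")
        man = man.assign(file=paths)
        man.to_csv(os.path.join(out_dir, "manifest.tsv"), sep="\t", index=False)
        return man
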