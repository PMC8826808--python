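"""Local benchmark harness: warm-up, timed repeats, reported — never asserted.

Timings depend on the host; the harness reports the mean and coefficient of
variation of wall time per stage and leaves interpretation to the reader.
A single untimed dry run precedes the timed repeats so one-off costs
(allocator warm-up, BLAS thread spin-up, JIT-style caches) do not pollute
the measurements.
"""

from __future__ import annotations

import time
from typing import Callable

import numpy as np
import pandas as pd

from .coexpression import direct_loo_coexpression, init_moments, loo_coexpression

__all__ = ["bench", "benchmark_coexpression"]


def bench(command: Callable[[], object], repeats: int = 3,
          label: str = "run") -> pd.DataFrame:
    """Time a callable: one untimed warm-up, then ``repeats`` timed runs.

    Returns a table with one row per timed run plus a summary row carrying
    the mean and the coefficient of variation (std/mean) of wall time.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    command()  # dry run, excluded from timing
    rows = []
    for r in range(1, repeats + 1):
        t0 = time.perf_counter()
        command()
        rows.append({"stage": label, "run": r, "seconds": time.perf_counter() - t0})
    df = pd.DataFrame(rows)
    secs = df["seconds"].to_numpy()
    mean = float(secs.mean())
    cv = float(secs.std(ddof=0) / mean) if mean > 0 else 0.0
    summary = pd.DataFrame(
        [{"stage": label, "run": "mean", "seconds": mean},
         {"stage": label, "run": "cv", "seconds": cv}]
    )
    return pd.concat([df, summary], ignore_index=True)


def benchmark_coexpression(n_genes: int = 200,
                           ratios: tuple[float, ...] = (0.05, 0.25, 0.5, 1.0),
                           repeats: int = 3, seed: int = 0) -> pd.DataFrame:
    """On-line vs direct leave-one-out co-expression runtime crossover.

    For each sample:gene ratio, times computing every sample-deprived
    correlation matrix by rank-one downdates versus by full recomputation.
    The on-line path's advantage grows with the ratio; the observed
    speedups are hardware-dependent and only reported.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for ratio in ratios:
        n_samples = max(3, int(round(n_genes * ratio)))
        X = rng.standard_normal((n_genes, n_samples))

        def online_all() -> None:
            ms = init_moments(X)
            for i in range(n_samples):
                loo_coexpression(ms, X[:, i])

        def direct_all() -> None:
            for i in range(n_samples):
                direct_loo_coexpression(X, i)

        t_on = bench(online_all, repeats=repeats)
        t_di = bench(direct_all, repeats=repeats)
        mean_on = float(t_on.loc[t_on["run"] == "mean", "seconds"].iloc[0])
        mean_di = float(t_di.loc[t_di["run"] == "mean", "seconds"].iloc[0])
        rows.append({
            "ratio": ratio,
            "n_samples": n_samples,
            "online_seconds": mean_on,
            "direct_seconds": mean_di,
            "speedup": mean_di / mean_on if mean_on > 0 else float("inf"),
        })
    return pd.DataFrame(rows)
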