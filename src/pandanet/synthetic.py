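"""Synthetic motif/PPI/expression fixtures with controlled structure.

Every stage of the pipeline can be exercised without any download: a
Bernoulli motif prior with guaranteed row/column coverage, a symmetric
self-interacting PPI prior, and an expression matrix drawn from a
latent-factor model so the co-expression matrix has genuine low-rank
structure for message passing to exploit.  Generation uses NumPy's PCG64
generator seeded explicitly, so fixtures are byte-identical across
platforms.

``gen_case`` emits fixtures whose TF:gene aspect ratios follow three
reference problem sizes from human regulatory-network practice — 652 TFs x
1,000 genes ("small"), 652 x 27,149 protein-coding genes ("coding"), and
1,603 x 43,698 transcripts ("transcript") — scaled down by an arbitrary
factor, with a 127-sample population at full scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .preprocess import CooperativityPrior, ExpressionMatrix, RegulatoryPrior

__all__ = ["FixtureSpec", "gen_motif", "gen_ppi", "gen_expression", "gen_case", "PRESETS"]

PRESETS = {
    "small": (652, 1000),
    "coding": (652, 27149),
    "transcript": (1603, 43698),
}


@dataclass(frozen=True)
class FixtureSpec:
    """Dimensions and structure of one synthetic data set.

    ``motif_density`` / ``ppi_density`` are expected edge densities in
    (0, 1]; ``latent_factors`` controls the rank of the expression signal
    and ``noise_sd`` the per-gene independent noise on top of it.
    """

    n_tf: int = 20
    n_genes: int = 50
    n_samples: int = 20
    motif_density: float = 0.25
    ppi_density: float = 0.25
    latent_factors: int = 3
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")
        for name in ("motif_density", "ppi_density"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.latent_factors < 1:
            raise ValueError("latent_factors must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _tf_ids(n: int) -> list[str]:
    return [f"TF{i:04d}" for i in range(1, n + 1)]


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def _sample_ids(n: int) -> list[str]:
    return [f"S{i:04d}" for i in range(1, n + 1)]


def gen_motif(spec: FixtureSpec) -> RegulatoryPrior:
    """Bernoulli 0/1 motif prior; resampled until every TF has at least one
    target and every gene at least one regulator."""
    rng = np.random.default_rng(spec.seed)
    for _ in range(1000):
        M = (rng.random((spec.n_tf, spec.n_genes)) < spec.motif_density).astype(float)
        if M.sum(axis=1).min() >= 1 and M.sum(axis=0).min() >= 1:
            return RegulatoryPrior(_tf_ids(spec.n_tf), _gene_ids(spec.n_genes), M)
    raise ValueError(
        f"motif_density={spec.motif_density} too low to cover every TF and gene "
        f"at size {spec.n_tf}x{spec.n_genes}"
    )


def gen_ppi(spec: FixtureSpec) -> CooperativityPrior:
    """Symmetric 0/1 PPI prior with unit diagonal."""
    rng = np.random.default_rng(spec.seed + 1)
    n = spec.n_tf
    P = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    # density 0 is allowed here (identity prior); clip for the <= comparison
    P[iu] = (rng.random(len(iu[0])) < spec.ppi_density).astype(float) \
        if spec.ppi_density < 1 else 1.0
    P = P + P.T
    np.fill_diagonal(P, 1.0)
    return CooperativityPrior(_tf_ids(n), P)


def gen_expression(spec: FixtureSpec) -> ExpressionMatrix:
    """Latent-factor expression: gene profiles are loadings on shared
    sample-wise factors plus independent Gaussian noise.

    With ``noise_sd=0`` and one factor the matrix is rank one, so every
    gene pair is perfectly (anti)correlated.
    """
    rng = np.random.default_rng(spec.seed + 2)
    L = rng.standard_normal((spec.n_genes, spec.latent_factors))
    F = rng.standard_normal((spec.latent_factors, spec.n_samples))
    X = L @ F
    if spec.noise_sd > 0:
        X = X + spec.noise_sd * rng.standard_normal(X.shape)
    return ExpressionMatrix(_gene_ids(spec.n_genes), _sample_ids(spec.n_samples), X)


def gen_case(preset: str, scale: float = 1.0, seed: int = 0,
             **overrides) -> tuple[RegulatoryPrior, CooperativityPrior, ExpressionMatrix]:
    """A fixture whose TF:gene aspect ratio matches a named reference size.

    ``scale`` shrinks both dimensions (rounded to nearest, minimum 2) and
    the 127-sample population (rounded up, minimum 3).
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; valid: {', '.join(PRESETS)}")
    if not 0 < scale <= 1:
        raise ValueError(f"scale must be in (0, 1], got {scale}")
    n_tf0, n_genes0 = PRESETS[preset]
    n_tf = int(round(n_tf0 * scale))
    n_genes = int(round(n_genes0 * scale))
    if n_tf < 2 or n_genes < 2:
        raise ValueError(f"scale {scale} shrinks {preset} below 2x2 ({n_tf}x{n_genes})")
    n_samples = max(3, math.ceil(127 * scale))
    spec = FixtureSpec(n_tf=n_tf, n_genes=n_genes, n_samples=n_samples, seed=seed,
                       **overrides)
    return gen_motif(spec), gen_ppi(spec), gen_expression(spec)
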