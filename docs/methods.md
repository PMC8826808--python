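# Methods

## The message-passing model

PANDA treats network inference as consistency optimization over three
matrices sharing a TF/gene index: the motif prior W (TF×gene), the
cooperativity prior P (TF×TF, from protein–protein interactions, assumed
symmetric with unit diagonal), and the co-expression matrix C (gene×gene
Pearson correlation). The model's core assumption is that a true
regulatory edge should be supported three ways at once: the TF's
cooperativity profile should resemble the gene's regulator profile
(*responsibility*), and the TF's target profile should resemble the
gene's co-expression profile (*availability*).

Each iteration k:

1. `R = sim(P rows, W gene-columns)`, `A = sim(W TF-rows, C gene-columns)`,
   both TF×gene. The orientation convention (which axis of W each message
   compares against) is fixed here; it makes both messages commensurate
   with W entrywise.
2. `hamming = mean |W − (R+A)/2|`, evaluated **before** the update. If it
   is below the tolerance the loop stops without committing, so a
   tolerance larger than the initial gap returns the normalized prior
   unchanged after zero iterations, and `converged=True` always implies
   the final gap is below tolerance.
3. `W ← (1−α)W + α(R+A)/2` with learning rate α ∈ (0,1], default 0.1.
4. `P ← (1−α)P + α·sim(W rows, W rows)` and
   `C ← (1−α)C + α·sim(W cols, W cols)`, each with the diagonal of the
   similarity matrix replaced by
   `dim · std(off-diagonal entries of the row, ddof=0) · exp(2αk)`.
   Self-similarity carries no evidence; the exponentially growing
   diagonal progressively anchors each TF and gene to its own profile,
   which is what drives the messages toward copies of W and hence the
   fixed point.

Defaults: tolerance 1e-3 on the hamming statistic, iteration cap 200.
Hitting the cap is a warning, not an error — a partial network is still
scientifically inspectable. Everything is deterministic: the result is a
pure function of the inputs and the configuration.

## Normalization

Because W₀, P₀, C₀ live on different scales, each is standardized across
both rows and columns: `out = (zrow + zcol)/√2` with ddof=1 in both
directions. The 1/√2 keeps the sum of two unit-variance components at
unit variance. Entries in a zero-variance row (or column) fall back to
the other direction's z-score alone, still divided by √2; entries
degenerate in both directions are 0, so the output is always finite.
Genes with constant expression get 0 off-diagonal correlation and unit
diagonal in C₀. After normalization P and C are re-symmetrized by
averaging with their transposes — row-wise and column-wise z-scores of a
symmetric matrix agree in exact arithmetic but differ in the last bits,
and exact symmetry makes triangular half-storage lossless.

## Similarity metrics and the distance-injection rule

The default similarity is the modified Tanimoto form
`t(x,y) = xy′ / √(xx′ + yy′ − |xy′|)`, which is positively homogeneous of
degree 1 and satisfies `t(x,x) = ‖x‖`. The radicand cannot be ≤ 0 in
exact arithmetic but can be in single precision; such entries return 0,
the neutral similarity.

Seven conventional metrics are provided as alternatives. `cosine` and
`pearson` are already similarities in [−1, 1]. The five distances are
returned **negated** by `pairwise_similarity`, so that larger always
means more similar; negation is a monotone order-preserving choice, and
the convention (rather than, say, `1/(1+d)`) is deliberately the simplest.
`standardized_euclidean` scales each coordinate by the pooled std
(ddof=1) over the stacked rows of both inputs; zero-variance coordinates
are dropped (weight 0). `cityblock` is L1, `chebychev` is the maximum
absolute coordinate difference.

Inside the message-passing loop, the four scale-homogeneous distances
(euclidean, squared euclidean, city block, Chebychev) need one further
rule. Fed in raw, they admit no fixed point: the diagonal refresh grows
the state scale every iteration, a degree-1 homogeneous distance grows
with it, and the hamming gap diverges super-exponentially until overflow.
The package therefore standardizes these messages before the update —
R within each TF row, A within each gene column, the two directions in
which the growing P and C diagonals inject offsets — making the iteration
scale-free, and rescales the P/C state once its magnitude would start
costing double-precision digits inside the metric's accumulation
(threshold 1e6 for city block and squared Euclidean, whose accumulation
is linear or quadratic in the state scale; 1e12 for Euclidean and
Chebychev, whose square root / max compress it). Both rules are part of
the step definition and are covered by the scalar step oracle in the
test suite. The Tfunction, cosine, Pearson and standardized-Euclidean
paths use none of this.

## PUMA and SPIDER

PUMA models miRNA regulators, which repress targets post-
transcriptionally and do not form the protein complexes the P update
models: after every P update, the rows and columns of P indexed by the
declared miRNA regulators are reset to their normalized prior values.
The freeze granularity (full rows **and** columns) is this package's
convention. With an empty set the code path degenerates to a no-op
assignment, so PUMA is bit-identical to PANDA.

SPIDER masks the motif prior with 0/1 open-chromatin evidence **before**
normalization (`W₀ ⊙ mask`), then runs unchanged; an all-ones mask is
bit-identical to PANDA, and an all-zero mask yields a constant prior that
normalizes to zeros and still runs.

## Leave-one-out co-expression

LIONESS needs the gene–gene correlation matrix with each sample removed.
With all-sample moments m (mean), s (std, ddof=1) and Cov (covariance,
ddof=1) computed once, the sample-deprived quantities follow by rank-one
downdates with m-centered deviations `d = Gᵢ − m`:

```
m_i     = (n·m − Gᵢ) / (n−1)
s_i²    = ((n−1)·s² − n/(n−1)·d²)            / (n−2)
Cov_i   = ((n−1)·Cov − n/(n−1)·d d′)          / (n−2)
C_i     = Cov_i / (s_i s_i′)
```

The ddof=1 convention is what makes the (n−1)/(n−2) structure exact, and
n ≥ 3 is required by the n−2 denominator. Published statements of these
downdates sometimes appear with other centerings or factors that do not
reproduce the left-out-sample statistics; the operative definition here
is *equality with direct recomputation on the retained n−1 samples*, and
the direct path (`direct_loo_coexpression`) is kept in the package as the
oracle — the two agree to ~1e-14 on double-precision fixtures, asserted
at 1e-10. Negative variance radicands from cancellation are clamped to
zero; entries involving a gene constant in the retained samples are 0
with unit diagonal.

LIONESS then interpolates `W_i = n(W_all − W_minus_i) + W_minus_i`.
The motif and PPI priors are normalized once and shared by all
per-sample runs; only C is recomputed and renormalized. Sample batching
is a round-robin plan over 1-based indices; workers receive only index
lists and return only result matrices, and the output is invariant to the
worker count and to splitting the range into consecutive sub-runs. A
failing sample is recorded in a failure manifest and the run continues —
one bad sample should not lose a cohort.

## Backends, precision, checkpointing

The engine talks to a backend through a small surface: stage inputs once,
compute pairwise similarities, fetch the result once. The `reference`
backend is plain NumPy; the `tiled` backend evaluates pairwise similarity
in fixed-size row blocks, which changes BLAS summation order and hence
genuinely exercises the equivalence contract (agreement within 1e-6 in
double precision). Staging enforces an optional byte budget
(rows·cols·width per matrix) and can hold the symmetric C as one
triangular half plus diagonal, halving bytes at rest with reads of (i,j)
and (j,i) returning the same value.

Precision is fixed per run: `single` casts the staged inputs to float32
and all loop arithmetic stays in float32 (scalars are applied as Python
floats, which NumPy treats as weak types); `double` is float64.
Accumulations are not promoted — a mixed-precision mode was considered
and left out to keep the precision contract simple; the observed
single-vs-double gap on the 20×50 fixture is ~4e-6 (asserted < 1e-3).

Checkpoints snapshot (k, W, P, C) to HDF5 every 10 iterations (and on
request), keyed by a SHA-256 digest of the configuration and the input
matrices; restoring under a different configuration is refused. Because
the loop state fully determines the remainder of the run, interrupt +
restore + continue is bit-identical to an uninterrupted run on the same
backend and precision.

## Synthetic data

The generator produces the three inputs with controlled structure, all
from an explicitly seeded PCG64 generator so fixtures are identical
across platforms:

* motif — Bernoulli 0/1 at the requested density, resampled until every
  TF has a target and every gene a regulator (default density 0.25);
* PPI — symmetric Bernoulli with unit diagonal (default 0.25);
* expression — a latent-factor model: gene loadings (standard normal) on
  a small number of shared sample factors plus independent Gaussian
  noise (defaults: 3 factors, noise sd 1.0). This gives C₀ genuine
  low-rank structure for the messages to exploit; with one factor and no
  noise every gene pair is perfectly correlated.

`gen_case` scales three reference problem shapes from human regulatory
genomics — 652 TFs × 1,000 genes, 652 × 27,149 protein-coding genes,
1,603 × 43,698 transcripts — by a shrink factor, with a 127-sample
population at full scale (rounded up, minimum 3).

What the generator does **not** emulate: count-like expression
distributions, motif genomic coordinates, chromatin signal, realistic
PPI topology (hubs, cliques), or TF autoregulation structure. Passing
tests therefore demonstrate algorithmic correctness, determinism and
numerical behaviour — not biological accuracy of inferred edges, which
is outside this package's scope.

## Problem sizes used by the tests and the acceptance script

The reference fixture is 20 TFs × 50 genes × 20 samples; the LIONESS
population fixture is 10 TFs × 30 genes × 12 samples; the step oracle
runs at 3×4. These sizes keep the full suite and the acceptance script
in the seconds range while exercising every code path; all contracts are
size-independent.

## Known limitations

* Convergence of the scale-homogeneous distance metrics at α = 0.1 is
  occasionally marginal: on some random fixtures the city-block run
  stalls just above the 1e-3 tolerance within 200 iterations (the gap
  keeps drifting with the diagonal refresh). The Tfunction default is
  robust in all observed runs.
* Under `standardized_euclidean` the fixed point is nearly edge-uniform
  (W converges to an almost constant matrix): its pooled standardization
  shrinks the informative spread. It is provided for benchmarking, not
  recommended for inference.
* The per-sample LIONESS loop is serial within a process; the worker
  abstraction is a deterministic scheduling contract, not an
  implementation of process- or device-level parallelism.
* Edge weights are consistency scores on a z-score-like scale, not
  probabilities; comparisons are meaningful within a run, not across
  differently normalized inputs.
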