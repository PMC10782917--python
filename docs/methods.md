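# Methods

## Model

Spots are embedded by a symmetric graph-convolutional auto-encoder. The
input is the spot × D matrix of principal-component scores X (D = 50). For
a mini-batch of n spots, two symmetric nonnegative adjacency matrices with
unit diagonal are built: W_e from Euclidean distances between PC vectors
and W_p from distances between tissue coordinates, both with the Gaussian
kernel exp(−d²/2l²). The encoder smooths over the two graphs in sequence,

    H1 = ELU(W_e X B1),    H2 = ELU(W_p H1 B2),

and the decoder applies the sharpening counterpart 3I − W in reverse order
with transposed projections, so the decoder owns no parameters: the model
has exactly 2·D² trainable scalars. The ablation variants `exp_only` /
`spa_only` keep a single view and a single D² projection. The training
objective is the reconstruction error of the PCs; we optimize its
mean-squared form (Frobenius² divided by the entry count), a monotone
rescaling that keeps SGD step sizes independent of batch size and D, and
report the Frobenius norm where a scalar loss is displayed.

The assumption underlying the architecture is that spots belonging to one
spatial domain are close both in expression space and in the tissue plane;
smoothing over both graphs pulls their embeddings together, while the
sharpening decoder prevents the trivial constant embedding by requiring
neighbor-contrast information to survive the bottleneck.

## Adaptive bandwidth and exact sparsity

The kernel bandwidths are derived per batch: l = d_τ / √(−2m), where d_τ is
the τ-quantile (default τ = 0.07 for both views) of the batch's
off-diagonal pairwise distances and m is the underflow constant of the
working precision — the largest integer with exp(m) = 0 (−104 in binary32,
−746 in binary64; probed at runtime rather than hard-coded). Entries at
distance ≥ d_τ then underflow to exact zeros, so the fraction of nonzero
off-diagonal entries equals τ up to quantile interpolation granularity
(≤ 2/(n(n−1))) in every batch. Numerical choices at the threshold:

- The quantile population is the off-diagonal entries only; including the
  diagonal's n structural zeros would bias d_τ low at small n. A flag
  restores the full-matrix population.
- The exponent is evaluated as m·(d/d_τ)², which is exactly m at d = d_τ
  despite rounding, rather than −d²/(2l²) which can land one ulp off.
- IEEE exp underflows to zero for all arguments below ln(minsubnormal/2),
  not only at integer exponents, so kernel values for distances within
  ≈ 0.1 % of d_τ would flush to zero as well. These entries are rounded up
  to the smallest subnormal of the working precision (a faithful rounding
  of their true magnitude), making the support of W exactly {d < d_τ}.
- A batch whose relevant distances are all zero (e.g. duplicated
  coordinates) has no bandwidth and raises a degenerate-batch error.

Adjacencies are evaluated in single precision by default (the convention of
GPU implementations of this model family; double precision is a flag),
stored sparse above 64 spots with zeros dropped, and upcast to double for
the linear algebra.

## Training

Plain SGD (momentum available but off), batch size 2000, 100 epochs by
default, learning rate 0.2 stepping to 0.1 at epoch `epochs − 19` — i.e.
the final rate for the last 20 epochs. Batches are a fresh uniform random
partition each epoch, derived from the run seed, so runs are exactly
reproducible; the quantile-calibrated bandwidth is what makes random
batches viable, since every batch gets the same neighbor density
regardless of composition. ⌈N/n⌉ batches per epoch; a trailing singleton
batch, which cannot carry a graph, is merged into its predecessor.

Within the training step the adjacencies are symmetrically degree
normalized (Deg^{−1/2} W Deg^{−1/2}) by default. The literal model
equations use W unnormalized, and `normalization="none"` restores that
behavior, but an unnormalized Gaussian adjacency at n = 2000 and τ = 0.07
has row sums around 140, which multiplies activations by ~140 per layer
and makes SGD at the published learning rate diverge immediately;
normalization bounds the smoothing operator's spectral radius by 1 and is
the package's default operating mode. The decoder sharpens the normalized
matrix. The final decoder activation is ELU like every other layer; a
linear-output flag exists because PC scores extend below −1 while ELU's
range is (−1, ∞), but in practice the leading PCs of log-normalized data
are well inside the representable range and the flag is off by default.

Gradients of the loss with respect to B1 and B2 are derived analytically
(the adjacencies are symmetric, which collapses the transposes) and
verified against central finite differences in the test suite at relative
tolerance 1e-4.

Embedding extraction runs the encoder over sequential, unshuffled batches
of the training batch size. Embeddings depend mildly on batch composition
— inherent to per-batch graphs — and the fixed sequential split makes them
bit-reproducible across calls.

## Clustering, refinement, markers

With a known domain count k, a full-covariance Gaussian mixture (EM, 5
seeded restarts, best likelihood kept, maximum-posterior assignment) is
fitted to the embeddings. This stands in for mclust-style model-based
clustering; mclust's model-family selection sweep is not replicated.
Without k, Louvain modularity optimization (resolution 1.2) runs on the
symmetrized kNN graph of the embeddings (default 15 neighbors); the
community count follows from the partition.

Refinement polls each spot's k = 6 nearest spatial neighbors (the
hexagonal neighborhood of Visium arrays, and a reasonable default for
gridded high-resolution data; a radius-based notion of "surrounding" would
be the natural alternative and is deliberately not implemented to keep one
well-tested code path). All votes use the pre-pass labels (one
simultaneous update); a spot relabels only when its own label is held by
at most half of the neighbors *and* another single label by strictly more
than half, so ties never flip a label. A single pass is the default;
`iterate=True` repeats to a fixed point, which on all test fixtures is
reached in a handful of passes. Refinement can only reuse existing labels,
so the number of distinct domains never grows.

Markers are one-vs-rest two-sided Wilcoxon rank-sum tests per domain and
gene: the exact null distribution when the pooled sample has fewer than 20
spots and no ties, otherwise the tie-corrected normal approximation
(vectorized over genes via a single ranking per gene; no continuity
correction, matching the convention of single-cell toolkits).
Benjamini–Hochberg adjustment is applied per domain across genes (a
global-family option exists). Fold changes are computed on
expm1-backtransformed means of the log-normalized values.

## Synthetic data

The generator emulates laminar tissue: spots on an integer grid (≈√N per
side), domains as K horizontal bands (or concentric rings binned by radius
quantiles), each domain owning a private block of marker genes whose mean
count is raised from the baseline b to b·e^effect inside the domain.
Counts are Poisson by default or negative binomial with overdispersion θ
(var = μ + μ²/θ); an optional dropout mask zeroes entries uniformly.
Defaults — 3000 spots, K = 5 bands, 200 genes, 10 markers per domain,
effect 1.5 on the log scale, baseline 5, Poisson — give a signal strength
at which the published pipeline defaults should, and in the tests do,
recover the domains essentially perfectly (ARI ≥ 0.8 is the acceptance
bar; observed values are ≈ 1.0).

What the generator does not emulate: within-domain expression gradients,
spatially correlated noise, library-size variation across the slide,
irregular domain shapes, and cell-type mixtures within spots. Passing
tests therefore demonstrate the correctness of the machinery and the
qualitative behavior of the method, not its accuracy on real tissue.

## Problem sizes in the test and acceptance runs

Unit tests use 60–500-spot fixtures. The end-to-end checks run the default
3000-spot synthetic tissue for 30 epochs (the loss has long plateaued
there), five seeds for the recovery check; the memory-contract check runs
one epoch at N ∈ {2000, 8000, 32000} with n = 1000 and D = 10, comparing
peak allocation inside the training loop via tracemalloc. The sparsity
recomputation in `scripts/acceptance.py` uses 20 batches of 500 spots with
uniform random coordinates and 50-dimensional features.

## Known limitations

- Embeddings are batch-composition dependent at inference; the sequential
  split fixes them but a different batch size changes them slightly.
- GMM clustering is an approximation to mclust (single covariance family).
- Exact Wilcoxon p-values are only used for very small samples; ties always
  route to the asymptotic path.
- No histology-image channel, no cross-slide batch correction, no global
  whole-dataset graph mode.
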