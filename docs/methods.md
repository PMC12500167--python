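# Methods

## Flow framework

Data vectors `x ∈ R^d` (log-normalized expression over selected genes) are
mapped through a chain of invertible layers to a latent `z ~ N(0, I_d)`.
The model density follows the change-of-variables rule
`log p(x) = log p_z(z) + Σ_l log|det J_l|`, with
`log p_z(z) = -½(‖z‖² + d log 2π)`, and is trained by minimizing the mean
negative log-likelihood.  Sampling inverts the invertible layers on
standard-normal draws.

### MAF layer

Each coordinate is transformed as `z_i = (x_i - μ_i(x_<i)) / σ_i(x_<i)`.
The conditioner is a single masked MLP (one ReLU hidden layer) in the MADE
style: hidden units carry degrees `1..d-1`, an input connects only to
hidden units of degree at least its own, and output `i` connects only to
hidden units of degree below `i`, which makes autoregressivity an exact
structural property (the path-count matrix between inputs `j ≥ i` and
output `i` is identically zero).  Positivity of `σ` uses an exponential
link — the conditioner emits `α_i` and `σ_i = exp(α_i)` — chosen for
numerical stability; the log-determinant is then simply `-Σ α_i`.  Density
evaluation needs one conditioner pass; inversion runs `d` sequential
passes.  The conditioner's output weights are zero-initialized, so a fresh
layer is exactly the identity.  Multi-layer stacks insert seeded feature
permutations between layers; the default depth is a single layer, which a
hyperparameter search over {1,2,3,4} layers, {128,256,512,1024} hidden
features and learning rates {1e-2,1e-4,1e-6} had selected together with
1024 hidden features and rate 1e-6 over 100 iterations.  Those selected
values are the `TrainConfig` defaults; the optimizer (Adam, with SGD
selectable), the reading of "iterations" as full data passes, and the
batch size of 256 are this package's choices where the protocol left them
open.

### Mixture-of-experts flow

One block is `[ActNorm, MoE coupling, ActNorm, MAF]`; the full model is a
contextual feature mask followed by `n_blocks` such blocks (default 1,
mirroring the single-layer MAF optimum).

**Contextual feature masking.**  A shallow MLP produces
`c = sigmoid(W_m ReLU(W_c x + b_c) + b_m)` and `m = 0.5·c ∈ (0, 0.5)^d`;
the masked input is `x' = x ⊙ (1-m) + x̄·m` with `x̄` the scalar mean of
the cell's feature values, so every masked value is a convex combination
of the original value and the cell mean.  The step is not invertible and
has no Jacobian term; it is treated as a learnable preprocessor: applied
on the density/training path, excluded from the log-determinant, and never
applied when sampling.  This is the only treatment consistent with an
exact-likelihood model, and it means generated cells come from the
invertible stack alone.

**ActNorm.**  `y = s ⊙ x + b` with `log|det J| = Σ log|s_j|`; it can be
disabled (identity, logdet 0).  Initialization is data-dependent: an
enabled layer behaves as the identity (`s=1, b=0`) until the trainer
standardizes it against the activations the first training batch produces
at its depth, after which `s` and `b` train freely.  Internally
`log|s|` is computed as `½ log s²` so the gradient exists for either sign.

**MoE attention coupling.**  An alternating binary mask `M` splits features
into a pass-through set `x_a = x ⊙ M` and a transformed set
`x_b = x ⊙ (1-M)` (both kept at full length `d` with zeros off-partition;
blocks alternate which parity leads).  Each of `E` experts (default 4)
runs multi-head attention (default 10 heads) over the a-set: each a-set
feature is one token, its scalar value linearly embedded to an embedding
of size 20 (divisible by the head count), attended, projected back to one
scalar per token.  A gate `g = softmax(W_g ReLU(U_g x_a) + b_g)` mixes the
experts, `h = Σ_e g_e h^(e)`.  Scale and shift heads map `h` linearly to
the b-set positions, `s = tanh(·)` and `t`, defined as 0 at a-set
positions, giving `z_a = x_a`, `z_b = x_b ⊙ exp(s) + t`, `z = z_a + z_b`
and `log|det J| = Σ_{j∈b} s_j`, bounded in magnitude by the b-set size.
The scale/shift heads are zero-initialized so the coupling starts at the
identity.  Attention is quadratic in the a-set size; for very large gene
panels this memory wall is a known limitation and no sparse-attention
workaround is provided.

Feature-wise tokenization, the gate hidden size (default 64), the mask
MLP hidden size (default 64), and the per-head key/query dimensionality
(embedding size / heads) are design choices where the architecture was
genuinely open; all are exposed in `MoEConfig`.

### Training

Adam on the mean NLL, seeded shuffling, full-batch when the data is
smaller than the batch size.  Zero-variance features (common in small cell
types after gene selection) receive seeded Gaussian jitter of scale 1e-6
with a warning, preventing scale collapse.  A non-finite loss aborts with
the loss history attached.  Two runs with the same seed are bitwise
identical.

## Generation protocols

**Q3 balancing.**  Q3 is the linear-interpolation 0.75-quantile of the
per-class cell counts, rounded half-up to an integer (the convention was
unstated; half-up reproduces integer targets).  Each class's synthetic
target is `max(0, Q3 - observed)`; one flow is fitted per class needing
synthesis, on that class's rows only, and the pooled real+synthetic count
of every class is exactly `max(observed, Q3)`.  Per-class training
inherits one global `TrainConfig`; child seeds derive from the config seed
through a seed sequence.

**Matched generation.**  For benchmark settings without labels, a single
flow fitted on the whole training matrix generates as many cells as the
test set.

**Proportional subsampling.**  Quotas are `floor(n·p_type)` with the
remainder distributed one each to the largest fractional remainders (ties
broken toward the larger class, then label order — a deterministic rule
chosen here); sampling is uniform without replacement within type.

## Metrics

- **WD**: per-feature 1-D Wasserstein-1 via the discrete empirical-CDF sum
  over pooled sorted unique values, averaged over features; tests
  cross-check it against an independent quantile-based oracle.
- **CD**: mean absolute entrywise difference of Pearson correlation
  matrices, diagonal included; zero-variance columns contribute
  correlation 0 by convention (warned).
- **MMD**: biased V-statistic with kernel `exp(-‖x-y‖²/(2ℓ²))`, averaged
  over length scales (0.005, 0.01, 0.1, 0.5, 1, 2); the biased form makes
  `MMD(X, X) = 0` exact.  "Length scale" is read as ℓ in the kernel above;
  the report metadata records the scales used.  A linear kernel is
  selectable.
- **Classification**: precision/recall/F1 from one-vs-rest confusion
  counts, macro-averaged by default (micro/weighted selectable and named
  in every report); accuracy is the overall fraction correct; a class
  never predicted has precision 0.
- **Batch silhouette**: `1 - |S|` with S the mean Euclidean silhouette
  over batch labels, in whatever representation the caller provides
  (PC-50 upstream); near 1 means well-mixed batches.
- **RMSE**: elementwise for arrays; keyed tables (e.g. per interaction
  pair × ligand–receptor mean) align on the key intersection, whose size
  is logged.

## Evaluation pipeline

Stratified, seeded 5-fold cross-validation (stratification is used so
every cell type appears in every fold's training set, as per-type
generation requires; an unstratified mode exists).  Per fold: highly
variable genes and the 50-component PCA basis are fitted on the fold's
real training rows only and applied to everything else — keeping the
representation independent of the generator under evaluation — then flows
are fitted per type, the Q3 pool is generated, WD/CD/MMD are computed for
baseline (train vs test) and balanced (pool vs test) arms, and a
100-tree entropy random forest is trained on the original and on the
pooled rows.  A structural audit records the row indices every generator
fit saw and errors if any lies outside the fold's training matrix.  Fold
averages are arithmetic means.

The marker filter (`unique_top_degs`) consumes a precomputed
differential-expression table, keeps genes with adjusted p < 0.05 and
log2 fold change > 1, ranks by descending log2FC (ties by smaller adjusted
p, then gene id — a deterministic refinement), cuts to the top 20 per
type, and removes genes shared between types' lists.  Computing the
differential-expression statistics themselves is out of scope.

## Synthetic data generator

`simulate_fixture` emulates the structure the models consume: gene base
means drawn log-normally (scale 0.5, σ=1, giving low-expression-dominated
panels), gamma-Poisson (negative binomial) counts with inverse-dispersion
2, Bernoulli dropout 0.3 for sparsity, geometric class-size decay with
ratio 0.368 across 4 types (a ~20:1 majority:minority spread), 10 marker
genes per type up-shifted 4-fold within that type, and an optional
per-batch log-normal multiplicative shift.  Defaults (2000 cells, 200
genes) are the conditions under which the benchmark properties are
asserted.  The generator does not emulate ambient RNA, doublets,
cell-cycle structure, or realistic gene-gene co-regulation beyond marker
blocks, so passing tests demonstrate correctness of the machinery and the
qualitative imbalance-rescue effect, not fidelity claims about any real
tissue.

## Numerical choices and problem sizes

Everything runs in float64.  Round-trip tolerances are 1e-5 (layer
inversions), 1e-4 (analytic vs finite-difference Jacobian
log-determinants), 2% (quadrature normalization of a trained 1-D
density).  The test suite and acceptance script use deliberately small
problem sizes — 2000×200 fixtures reduced to 100 highly variable genes,
hidden widths 16–64, 40–200 epochs at learning rates 0.01–0.05 — which
train in seconds while exercising every code path; the package defaults
remain the selected full-scale setting (1024 hidden, 1e-6, 100
iterations).

## Known limitations

Attention memory grows quadratically with the pass-through feature count;
no conditional (label-embedding) flow, batch-effect correction, GPU path,
or scran-style deconvolution normalization (library-size/median factors
are the default, with a hook for externally computed factors).
Mitochondrial/ERCC QC needs caller-supplied per-cell fractions and is
otherwise skipped.
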