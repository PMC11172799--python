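# Methods

## Overview

`sczag` clusters scRNA-seq count matrices by combining four ingredients:

1. **ZINB autoencoder.** Raw counts of the selected highly variable genes
   are modeled per entry as a zero-inflated negative binomial
   ZINB(x; π, μ, θ) = π·δ₀(x) + (1−π)·NB(x; μ, θ). A decoder maps the
   latent embedding through a shared ReLU trunk (128 → 256 → 512) to three
   output heads: π = sigmoid(·), μ = exp(·), θ = exp(·). The reconstruction
   loss is the mean per-entry negative log-likelihood.
2. **Personalized-PageRank propagation encoder.** A two-layer dense map
   (input → 128 → 15, ReLU then linear) produces predictions H; a
   truncated power iteration Z⁽ᵏ⁺¹⁾ = (1−α)·Â·Z⁽ᵏ⁾ + α·H over the
   self-looped, symmetrically normalized KNN-graph adjacency Â diffuses
   them. The fixed point is α(I − (1−α)Â)⁻¹H, so the embedding blends each
   cell's own prediction with an exponentially decaying average of its
   graph neighborhood.
3. **Adaptive graph-contrastive learning.** Two stochastic views are drawn
   each epoch by removing edges and masking feature dimensions with
   probabilities that decrease with PageRank centrality, so peripheral
   structure is perturbed preferentially. A multi-view InfoNCE objective
   (cosine similarity of two-layer-ELU-projected embeddings, temperature
   τ) pulls the two views of each cell together against intra- and
   inter-view negatives.
4. **Self-optimizing clustering.** After pretraining, cluster centers are
   seeded by spectral clustering of the embedding. Soft assignments use a
   Student's-t kernel q_iu ∝ (1 + ‖z_i − μ_u‖²)⁻¹; an auxiliary target
   p_iu ∝ q_iu²/f_u (f_u the soft cluster mass) sharpens them, and the
   clustering loss is KL(P‖Q), with gradients flowing into both the
   encoder and the centers.

Training is full-batch Adam in two phases: pretraining minimizes
L = L_ZINB + λ_c·(−J) (1000 epochs, lr 1e−4 by default) and main training
adds λ_k·KL(P‖Q) (300 epochs, lr 5e−4), refreshing P from the current Q at
the start of every epoch and redrawing the two augmented views every
epoch. The ZINB and clustering branches always read the un-augmented
graph's embedding; only the contrastive branch sees the views.

## Preprocessing

Genes never expressed, or expressed (nonzero) in fewer than
`min_cell_fraction` (default 1%) of cells, are removed. Counts are
normalized per cell to the median library size m(X) and log-transformed:
N(X)_ij = ln(1 + m(X)·x_ij / Σ_o x_io), which keeps zeros at exactly zero
and all entries finite. Highly variable genes (default top 500) are ranked
by a Seurat-style normalized dispersion: on the expm1 scale, per-gene
dispersion var/mean is z-scored within 20 mean-expression bins; genes in
singleton bins score 0 and zero-variance genes rank last. Ties break
toward the smaller gene index so selection is deterministic, and top-k
selections are nested in k.

## Graph construction

The cell graph is a union-symmetrized K-nearest-neighbor graph (default
K = 15) under Euclidean distance on the HVG-normalized matrix: an edge
exists when either endpoint lists the other among its K nearest. All edges
have weight 1; self-edges are excluded; distance ties at the k-th neighbor
resolve to the smaller cell index. Propagation uses
Â = D̃^(−1/2)(A + I)D̃^(−1/2), whose spectrum lies in [−1, 1] and which
satisfies Â√d̃ = √d̃.

## Augmentation probabilities

Node centrality is the unnormalized PageRank score solving
σ = α·A·D⁻¹·σ + 1 on the bidirected graph (damping α = 0.85, fixed-point
iteration to 1e−10, cap 1000 iterations; all scores ≥ 1). Edge centrality
is the endpoint mean, feature-dimension importance the centrality-weighted
sum of absolute feature values; both are taken through log before
normalization. Probabilities follow
p = min(((s_max − s)/(s_max − μ_s))·p_base, p_τ): an item at the mean
importance receives exactly p_base and the most important item 0. When all
scores coincide the 0/0 ratio is assigned its continuous limit 1. All-zero
feature columns are clamped to a 1e−12 weight floor before the log, which
gives them the maximum masking probability. Defaults: p_e = 0.3/0.4 and
p_f = 0.1/0.2 for views 1/2, truncation p_τ = 0.7 — conventional values
for centrality-adaptive augmentation; the method names these parameters
but fixes none of them. Probabilities are computed once from the original
graph; only the Bernoulli draws are repeated each epoch.

## Numerical choices

* The propagation teleport α (default 0.1) and step count K (default 10)
  are distinct from the 0.85 centrality damping; both follow the usual
  propagation-encoder convention and are configurable. The
  classification-style row softmax after the final step is off by default
  (a probability simplex is the wrong geometry for latent clustering);
  `final_softmax=True` restores it.
* ZINB outputs are clamped to π ∈ [1e−6, 1−1e−6] and μ, θ ∈ [1e−5, 1e6];
  the x = 0 mixture term is computed with logaddexp. With π = 0 the loss
  reduces exactly to the plain NB likelihood.
* The InfoNCE denominator is evaluated with a log-sum-exp whose
  self-similarity entry is masked by a −1e30 additive constant;
  zero-norm projected vectors are given similarity 0.
* Reconstruction targets the **raw counts** of the selected HVGs, not the
  normalized values — a ZINB models counts. No size-factor scaling is
  applied to μ, mirroring the decoder's plain exp head.
* Cluster-center initialization uses seeded spectral clustering with an
  RBF affinity; if a cluster comes back empty the seed is shifted once
  before raising.
* All weights are Glorot-uniform with seeds derived from the single run
  seed via `numpy.random.SeedSequence` spawning, so augmentation draws,
  initialization and spectral clustering are independently reproducible.
* Gradients are computed by reverse-mode automatic differentiation over
  numpy arrays (the `autograd` package) and applied with a hand-rolled
  full-batch Adam (β = 0.9/0.999, no weight decay). The training loop
  holds its arrays in float32 — counts are small integers, exact in single
  precision — which roughly quadruples throughput; preprocessing and all
  public module functions are float64.

## Ablation switches

`use_appnp=False` replaces the propagation encoder with a conventional
two-layer graph convolution (ReLU(Â·X·W₁), then Â·h·W₂) of the same widths.
`use_augmentation=False` disables the contrastive branch entirely.
`use_zinb=False` replaces the likelihood with mean-squared reconstruction
of the normalized features through the same decoder trunk and a linear
head. All variants keep interfaces, seeds and the rest of the loss intact.

## Synthetic data

The generator plants cluster structure in ZINB noise: cells are assigned
to clusters by fixed proportions (largest-remainder rounding, then a
seeded shuffle); each cluster owns a disjoint block of DE genes (fraction
`de_fraction` of all genes) whose baseline mean is multiplied by
exp(±log_fold_change) with random signs; counts are drawn NB(μ, θ) and
zeroed independently with probability `dropout_pi`. Named fixtures:

| fixture | cells × genes | clusters | lfc | dropout | character |
|---|---|---|---|---|---|
| tiny  | 60 × 100   | 2 | 2.0 | 0.2 | smoke-test size |
| easy3 | 300 × 800  | 3 | 2.0 | 0.3 | clearly separable |
| hard6 | 600 × 1200 | 6 | 0.8 | 0.5 | weak signal, heavy dropout |

Baseline mean 2.0 and dispersion 2.0 are typical magnitudes for highly
variable genes in droplet data. The generator deliberately omits library
-size variation, batch effects and trajectories; passing tests on these
fixtures therefore demonstrates correct mechanics and recoverability of
planted mean-shift structure, not performance on real tissue atlases.

## Problem sizes and what the experiments show

The synthetic experiments run a reduced schedule (pretrain 100 / main 50
epochs — the `--fast` profile, also available on the CLI; the ablation
grid uses pretrain 60 / main 30 per run), not the full 1000 + 300
default. On `easy3` the full pipeline recovers the planted
3-cluster structure essentially perfectly (ARI ≈ 1) across seeds.

`hard6` probes the regime where the KNN graph itself is unreliable: with
lfc 0.8 and 50% dropout only ≈30% of KNN edges connect cells of the same
cluster (chance ≈17%), and a PCA + k-means baseline reaches ARI ≈ 0.4
while purely graph-propagated embeddings stay near chance. This regime is
informative about the method's failure mode — when the graph is mostly
noise, graph diffusion and graph-contrastive views inject more noise than
signal, and the full-batch ZINB autoencoder at the default learning rate
reduces the likelihood only marginally below a per-gene null, so the
latent space carries little cell-level information. The ablation
comparison on `hard6` is reported as a directional tendency and should be
read with that caveat.

## Known limitations

* Full-batch training: memory and time scale with cells × genes; no
  minibatching or neighbor sampling.
* The number of clusters is user-supplied; no model selection.
* Spectral initialization can fail on degenerate embeddings (collapsed to
  a point); the trainer warns when final hard labels populate fewer
  clusters than requested.
* CSV orientation is never inferred; callers must state it.
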