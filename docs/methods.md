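# Methods

`mdagcan` predicts microbe–disease associations by encoding both entity
types in one heterogeneous graph and decoding pairwise association scores
from the learned node embeddings. This note documents the model, the
parameters that matter, the synthetic data the tests run on, and the
numerical and design choices that are not forced by the method itself.

## Problem setting

The input is a binary association matrix **A** ∈ {0,1}^(nd×nm) with
diseases on the rows and microbes on the columns, assembled from a curated
catalog of published microbe–disease links. The task is matrix completion:
rank the unobserved (zero) cells so that true-but-unrecorded associations
appear near the top. Catalogs of this kind are extremely sparse (a few
hundred positives over thousands of cells) and have strongly skewed node
degrees, which drives several choices below.

## Similarities

**Gaussian interaction profile (GIP) kernel.** Each entity's profile is
its row (disease) or column (microbe) of **A**. The kernel is

    K(i, j) = exp(−λ ‖p_i − p_j‖²),   λ = λ′ / mean_t ‖p_t‖²,

with original bandwidth λ′ = 1. Dividing by the mean squared profile norm
adapts the bandwidth to association density: the sparser the catalog, the
wider the kernel. An all-zero matrix leaves λ undefined and is rejected.

**Functional similarity.** When gene (disease side) or protein (microbe
side) annotations are available, similarity between two entities is the
best-match average (BMA) over their gene sets: every gene contributes its
best score against the opposite set, both directions are pooled, and the
sum is divided by the total gene count. Gene–gene scores come from a
log-likelihood-score network min–max normalized to [0,1] over observed
off-diagonal scores; self-scores are fixed at 1 so identical sets score 1,
and absent pairs score 0 (no evidence). Entities without annotations have
functional similarity 0 against everything.

**Fusion.** Integrated similarity is GIP where functional evidence is
absent, otherwise the convex combination μ·GIP + (1−μ)·functional. The
conditional form matters: functional coverage is always partial, and the
fallback keeps the matrix fully populated.

## Heterogeneous graph

The two integrated similarity matrices are degree-normalized
(Ds^{−1/2} S Ds^{−1/2}; the diagonal of 1 guarantees positive row sums)
and placed on the block diagonal, scaled by a penalty β that balances
similarity edges against association edges:

    G_HN = [[β·DS*, A], [Aᵀ, β·MS*]],    H(0) = [[0, A], [Aᵀ, 0]].

H(0) is fixed and non-trainable; its width is nd+nm, so the first encoder
weight maps (nd+nm) → k. Divide-by-max block normalization is available
as a config option (`sim_norm: max`).

## Encoder–decoder

Each graph-convolution layer applies

    H ← tanh(D^{−1/2} G_HN D^{−1/2} H W),

with D the degree matrix of G_HN (two layers by default). A single-head
graph-attention layer then re-aggregates each node as an attention-weighted
average of its neighbors: scores e_ij = relu(aᵀ[W h_i ‖ W h_j]) over the
neighborhood {j : G_HN(i,j) > 0} ∪ {i}, softmax-normalized per row. The
self-loop guarantees a non-empty neighborhood. The decoder scores every
pair as Â = sigmoid(Z_d W′ Z_mᵀ).

Training minimizes the focal loss summed over all trained cells,

    ψ = −α (1−Â)^γ log Â        (positive cells)
    ψ = −α Â^γ log(1−Â)         (negative cells),

with Adam (β1 0.9, β2 0.999, ε 1e-8). No negative subsampling is done: the
(1−p)^γ / p^γ down-weighting of easy cells is the imbalance mechanism, and
the matrices are small enough for full-batch training. The weight α is
applied to both classes, exactly as the loss is defined above.

All forward and backward passes are implemented in NumPy with analytic
gradients; a finite-difference check through the entire
encoder–attention–decoder–loss chain is part of the test suite.

## Default hyperparameters

| parameter | default | meaning |
|---|---|---|
| μ | 0.5 | GIP weight in the fusion (dimensionless) |
| β | 8 | similarity-block penalty in G_HN |
| k | 64 | embedding dimension |
| lr | 5e-5 | Adam learning rate |
| α, γ | 0.1, 2 | focal loss weight and exponent |
| dp_node, dp_reg | 0.5, 0.7 | node / entry dropout (training only) |
| epochs | 500 | full-batch Adam steps |
| layers | 2 GCN + 1 GAT | encoder depth |

These are the grid-search optima reported for the method on the real
catalogs (hundreds of microbes, tens of diseases, 450–629 positives) and
are kept as the package defaults.

**Scale sensitivity.** Two of these defaults are tied to that data scale.
With full-batch Adam the per-step parameter movement is bounded by the
learning rate, so 500 steps at lr 5e-5 move every weight by at most 0.025
— on a small problem the ranking then never leaves its random
initialization. Likewise node dropout 0.5 combined with entry dropout 0.7
keeps only ~15% of feature entries per step, which a 90-node graph with
~150 positives cannot absorb. The desk-scale benchmark configuration
(`mdagcan.benchmark.benchmark_config`) therefore uses lr 5e-3, β 2 (both
inside the method's search grids), 1500 epochs and no dropout, with the
remaining parameters at their defaults. Users fitting catalogs of the original scale
should keep the published defaults.

## Dropout semantics

Node dropout zeroes whole rows of a layer's input (entire nodes removed),
entry dropout zeroes individual entries; both rescale by 1/(1−p) and act
only during training. Inference is fully deterministic.

## Cross-validation protocols

* **LOOCV** — every positive is zeroed in turn, the *entire* pipeline
  (GIP similarities, fusion, graph, training) is recomputed from the
  masked matrix, and the held-out score is pooled with that round's
  never-associated scores; one global AUC is reported.
* **k-fold** — positives are partitioned into k seeded folds (sizes differ
  by at most 1); per-fold metrics, mean ± sd reported.
* **Horizontal / vertical cold start** — 20% of disease rows (or microbe
  columns) are fully zeroed in training; all cells of the held-out rows
  are scored. Five seeded repeats, mean ± sd. The vertical protocol is the
  horizontal protocol run on the transposed matrix with the two
  functional-similarity inputs swapped, so the two mirror each other
  exactly by construction.

Masked positives are treated as negatives in the training loss (the
standard matrix-completion convention), and similarities are *always*
recomputed from the masked matrix — skipping that recomputation leaks
held-out labels through the interaction profiles, which the test suite
audits explicitly.

Threshold metrics (F1, accuracy, sensitivity, specificity) use a fixed 0.5
decision threshold by default, configurable via `threshold`.

## Synthetic data

The generator emulates what real catalogs look like to a structure
learner:

* diseases and microbes belong to latent communities (`latent_rank`
  clusters, one-hot directions plus 0.15 Gaussian perturbation);
* every entity has a gamma(2,1) association propensity multiplying its
  factor — this reproduces the heavy-tailed degree distributions of real
  catalogs and makes the planted structure identifiable from the matrix
  alone;
* the top fraction of factor inner products becomes 1, with the planted
  count corrected so that the *post-noise* expected density equals the
  `density` target; each cell is then flipped with probability `noise`;
* annotations are drawn per cluster from shared gene pools, with
  within-pool scores in [0.7,1.0], cross-pool in [0,0.2], and a 20%
  unannotated fraction to exercise the fusion fallback.

Defaults: nd 30, nm 60, rank 3, density 0.08, noise 0.02 — about twice the
density of the real catalogs, small enough that every protocol reruns the
full pipeline in seconds.

What the generator does **not** emulate: real taxonomies and gene
identifiers, the score distribution of curated gene networks, annotation
biases (well-studied diseases have more genes), or any dependence between
annotation coverage and association degree. Passing the synthetic
benchmark shows the pipeline recovers planted community structure at
realistic sparsity; it does not certify performance on any real catalog.

**Ceiling.** With density 0.08 and flip noise 0.02, roughly a fifth of the
observed positives are pure noise, so even an oracle ranking by the true
generative affinity only reaches AUC ≈ 0.83–0.91 depending on the seed.
The benchmark's pass line (mean 5-fold AUC ≥ 0.80 over five seeds) was
frozen after repeated calibration runs and sits deliberately close to that
ceiling.

## Numerical choices

* Scores are clamped to [1e-7, 1−1e-7] before any logarithm.
* Attention logits outside a neighborhood are set to −1e30 before the
  softmax (never exponentiated into NaN); each row is max-shifted.
* Similarity matrices are symmetrized by averaging after computation to
  remove float asymmetry; file readers warn above a 1e-8 discrepancy.
* Weights are Xavier-uniform, seeded through `numpy.random.default_rng`;
  identical seeds give bitwise-identical score matrices.
* Permuting entity order permutes all outputs consistently; equality holds
  to machine rounding (BLAS reduction order changes under permutation, so
  bitwise equality across a permutation is not guaranteed).
* Degenerate inputs fail loudly: all-zero association matrices (undefined
  GIP bandwidth), zero-degree graph nodes, single-class AUC inputs and
  non-finite losses all raise instead of imputing.

## Known limitations

* Full-batch dense linear algebra: fine for hundreds of nodes, not
  thousands (sparse propagation is deliberately out of scope).
* Single-head attention, fixed epoch count, no early stopping.
* The published-default configuration is appropriate at the real-catalog
  scale only; see "Scale sensitivity" above.
* Functional-similarity inputs are consumed as pre-extracted tables; no
  database download or identifier resolution is performed.
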