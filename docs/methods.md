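# Methods

`spagae` jointly infers spatially constrained cell–cell interactions (CCIs)
and refines cell-specific gene regulatory networks (GRNs) from imaging-based
spatial transcriptomics (seqFISH/MERFISH-scale panels: 100–200 genes, one to
a few thousand cells with 2D coordinates), using a multi-level graph
autoencoder.  This note describes the model, its assumptions, the synthetic
data generator, and the numerical choices that matter.

## Input graphs

**Cell level.**  Cells are vertices; edges come from a k-nearest-neighbour
search on the spatial coordinates, symmetrized by union (an edge exists if
either cell ranks the other among its k nearest).  Default k = 6 — a typical
contact number for 2D cell packings and comfortably above the common
assumption that a cell interacts locally with at least 3 neighbours.
Coordinates are used as given (2D Euclidean, no rescaling); distance ties,
including duplicate coordinates, break deterministically toward the lower
cell index.  Cell features X_c are the log(1+x) expression profiles.

**Gene level.**  Each cell carries a baseline GRN — a weighted g×g adjacency
from an upstream cell-specific inference method, or from the built-in
simulator.  Weighted GRNs are symmetrized by max(|w_ij|, |w_ji|) and
binarized; the default cutoff is the per-cell 90th percentile of the
off-diagonal weights (upstream methods emit dense weighted matrices; a
`top_q` rule and a fixed absolute threshold are available).  The n_c binary
GRNs are stacked block-diagonally into A_g over n_g = n_c·g gene vertices
(vertex v belongs to cell ⌊v/g⌋).  Cross-cell edges are then added from a
ligand–receptor (LR) table: for every *spatially adjacent* cell pair (i, j)
and every (ligand L, receptor R) pair present in the panel, undirected edges
(L@i, R@j) and (L@j, R@i).  Gene-level information therefore flows between
cells only where both spatial proximity and an LR channel exist.

**Gene features.**  Each gene vertex gets an f_g = 32 dimensional feature
describing its local network neighbourhood, in the node2vec spirit: 10
seeded random walks of length 80 per vertex (second-order p = q = 1 by
default), windowed co-occurrence counts (window 5), positive pointwise
mutual information (PPMI), and a factorization X = U√S of the PPMI matrix.
Two choices deserve emphasis:

- Walks run on the GRN blocks only by default (`scope="blocks"`), so gene
  features describe purely intracellular neighbourhoods; the LR cross edges
  enter through message passing, not through the features.  `scope="full"`
  is available.
- The PPMI matrix is factorized **per connected component**.  Walks never
  cross components, so the co-occurrence matrix is block-structured with
  roughly one component per cell; a single global rank-32 truncation would
  discard almost the entire per-component spectrum (total rank ≈ n_c·g) and
  leave the decoder unable to reconstruct any individual GRN block.
  Per-component factorization keeps each block's full spectrum within the 32
  columns, and matches how walk-based embeddings behave (components never
  share information).  Isolated vertices get zero rows; singular-vector
  signs are fixed deterministically.

## Model

Both levels are encoded by independent two-layer graph-convolution stacks
with the symmetric normalization

    Z^(l+1) = σ( D̃^{-1/2} (A + I) D̃^{-1/2} Z^(l) W^(l) ),

ReLU between layers, identity on the last (hidden 64, latent d = 32):
Z_c = E_c(X_c, A_c) ∈ R^{n_c×d} and Z_g = E_g(X_g, A_g) ∈ R^{n_g×d}.
Gene embeddings are aggregated per cell — mean pooling by default
(Z_g* ∈ R^{n_c×d}); concatenation in dataset gene order is available but
inflates the combined embedding to d(1+g) columns — and concatenated with
the cell embeddings: Z = [Z_c | Z_g*].

Both decoders are inner-product decoders: the edge probability for (u, v)
is logistic(⟨z_u, z_v⟩).  The cell decoder uses the combined Z; the gene
decoder uses Z_g only and is evaluated per pair list or per diagonal block —
the n_g×n_g reconstruction is never materialized.

## Objective and training

    L = λ_c · L_c + λ_g · L_g,   λ_c = λ_g = 1 by default.

**L_c** is binary cross-entropy on the training positives plus an equal
number of uniformly sampled non-edge negatives (1:1).  An all-pairs mode
with the 1/n_c² normalization exists for small graphs and for oracle tests;
the sampled form is the training default because all-pairs BCE is dominated
by the ~n² negatives.  Scores are clipped at ε = 1e-12 in the loss value
(the gradient uses the unclipped logistic form, which is exact).

**L_g** is mean squared error between the gene-level reconstruction and the
input GRN blocks, restricted to the block-diagonal mask (n_c·g² entries),
computed blockwise.  One deliberate numerical choice: the target blocks are
**A + I**, i.e. self-edges count as positives.  The inner-product decoder
scores every self-pair at logistic(|z_u|²) ≥ ½, so a zero-diagonal target
makes the collapsed embedding Z_g = 0 a local attractor (observed: the gene
loss pins at 0.25 and the branch never trains).  Reconstructing A + I is
the usual graph-autoencoder convention and removes the degeneracy;
`gene_loss(..., self_loops=False)` provides the literal zero-diagonal form.

**Protocol.**  A fraction (default 30%) of the unique proximity edges is
held out; the training propagation graph (cell level *and* the LR cross
edges of the gene level) is rebuilt from the remaining edges, so held-out
edges never leak into message passing.  Negatives are drawn once per run,
disjoint between train and test.  Optimization is full-batch Adam
(lr 0.01, 200 epochs default) with closed-form gradients (the model is
small enough that backpropagation is a handful of matrix products; a
finite-difference test guards the derivation).  Weights are Glorot-uniform
with a fixed seed; runs are bit-reproducible on CPU for a fixed seed.

**Conditioning.**  Expression features are standardized per gene (zero
mean, unit variance) before encoding.  Without this the initial decoder
logits sit deep in logistic saturation (|⟨z_i, z_j⟩| ≈ 30) and tens of
epochs are wasted un-saturating; with it, link-prediction AP on the
synthetic benchmark improves substantially.  The graph objects keep the
unstandardized log-expression for feature-vs-embedding comparisons.

**Noise robustness.**  The perturbation protocol adds ⌊r·m⌋ fake training
edges (uniform non-edges disjoint from all split sets) and/or removes
⌊r·m⌋ true training edges, r ∈ [0, 0.5], touching only the training list;
the perturbation applies to the cell-level training edges (a flag could
redirect it to gene-level LR edges, but the cell-level reading is the one
consistent with the rest of the protocol).

## Evaluation

- **Link prediction:** average precision (recall-weighted mean of
  precisions, no interpolation) and AUROC (Mann–Whitney; ties count half)
  on the held-out positives and matched negatives, via scikit-learn.
- **Refined GRNs:** cell i's refined GRN is the decoded diagonal block i
  (continuous scores in (0,1); optional binarization).  Against a known
  truth we report the AUPRC ratio — area under precision–recall divided by
  the positive density, diagonal excluded — so 1 ≈ random and higher is
  better.
- **Spatial refinement:** Spearman rank correlation between the cell–cell
  spatial distance matrix and a comparison distance matrix (embedding rows,
  feature rows, or Frobenius/flattened-Euclidean distances between per-cell
  GRN matrices), over the strict upper triangle, either entire or
  restricted to pairs inside the same block.  Blocks default to spatial
  communities (k-means on coordinates, k = 6), matching the reading of the
  block diagonal of a spatially ordered heatmap as "cells that are close
  together"; any label vector (e.g. k-means domains on embeddings) can be
  supplied instead.  P-values use the large-sample approximation.
- **Spatial domains:** k-means (default k = 6) on the combined embedding.

## Synthetic data generator

The generator stands in for a kinetic multi-omics simulator at desk scale;
it produces exactly what the pipeline consumes plus ground truth.  Per
configuration: cell types are assigned and placed (clustered layout: type
centroids in the unit square, Gaussian jitter σ = 0.08; or uniform); each
type gets a directed acyclic TF→target GRN sampled at `grn_density` with
signed weights (70% activating, |w| ~ U(0.5, 1.5)), symmetrized for the
binary ground truth; expression follows a linear structural model in
topological order — root genes lognormal with type-specific means, targets
the weighted sum of their regulators — with Gaussian noise (σ =
`noise_sd`) at every step and clipping at zero.  Ligands are drawn from
target genes and receptors from TFs; for every cell pair within
`interaction_radius` whose types form a compatible pair, each LR channel
adds `lr_effect` × (sender ligand level) to the receiver's receptor and,
scaled by the regulatory weights, to the receptor's targets.  Such pairs
are the ground-truth CCIs.  Supplied GRN priors are the per-cell truth with
⌊rate·|edges|⌋ edges flipped (removals and additions balanced) and random
weights on the surviving support — the stand-in for an imperfect upstream
GRN-inference step.

Named conditions: `tiny` (12×6, oracle tests), `easy` (200 cells × 20
genes, 3 types, strong clustering, corruption 0.2 — all directional
benchmarks), `realscale` (1597 cells × 125 genes, mirroring a seqFISH
mouse-cortex panel; used as a construction-scale smoke test).  These sizes
keep the full test suite and the acceptance script in the minutes range on
one CPU.

**What the generator does not emulate** — and hence what passing benchmarks
do and do not show: no transcriptional kinetics/bursting or count noise
(expression is continuous, post-normalization scale), no ligand diffusion
gradients (a hard interaction radius), no cell-type-specific LR usage
beyond pair compatibility, and GRNs identical within a type.  Success on
these conditions demonstrates that the machinery recovers planted spatial
and regulatory signal, not performance on real tissues.

## Known limitations

- **Refinement cannot beat a near-oracle prior.**  With 20% corruption the
  supplied priors are a ~90%-precision/recall classifier of the true GRN
  (AUPRC ratio ≈ 7.6 where the ceiling is ≈ 9).  Decoded continuous scores
  that merely reproduce the prior rank strictly below it on average
  (a binary scorer benefits from tie-grouping in average precision), and
  the shared-weight GCN does not pool across same-type cells strongly
  enough to denoise past it; measured upper bounds for any walk-based
  refinement of a single cell's corrupted graph (raw PPMI, path-count
  smoothing, even perfect decoder memorization) all sit below the prior.
  The refined GRNs do carry genuine signal (AUPRC ratio ≈ 4 vs 1 for
  random) and become more spatially organized than the priors, but
  "refined ≥ strong prior" should not be expected in this regime — the
  regime where refinement wins is a *weak* prior, which is also the regime
  real upstream methods occupy.
- **Entire-matrix embedding/location correlation is seed-dependent.**  The
  generator's LR field plus type clustering can make raw expression itself
  strongly spatially correlated; sampled-pair BCE training sharpens
  neighbour/non-neighbour discrimination but flattens long-range distance
  gradation, so the entire-matrix Spearman of embeddings does not always
  exceed that of the raw features (the within-neighbourhood comparison
  does, robustly).
- Full-graph training only (no mini-batching); fine for panel-scale data.
- GRNs are treated as undirected after binarization; no directed semantics.
- No variational encoder or attention variants; the decoder is the plain
  inner product (a cosine variant is noted in the code but not default).
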