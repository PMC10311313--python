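# spagae

Joint inference of **cell–cell interactions (CCIs)** and refinement of
**cell-specific gene regulatory networks (GRNs)** from spatially resolved
single-cell transcriptomics, with a multi-level graph autoencoder.

Imaging-based spatial transcriptomics (seqFISH, MERFISH) gives per-cell
expression of a gene panel plus 2D coordinates.  Extracellular signaling is
mostly ligand–receptor mediated and spatially constrained, and it feeds the
receiving cell's regulatory network — so CCI inference and GRN inference are
one problem, not two.  `spagae` models both levels at once:

- a **cell graph** G_c: cells as vertices, spatial kNN edges (A_c), log
  expression as features (X_c);
- a **gene graph** G_g: every cell's (binarized) baseline GRN stacked
  block-diagonally into A_g over n_c·g gene vertices, augmented with
  ligand–receptor edges between spatially adjacent cells, and node2vec-style
  random-walk features (X_g).

Two parallel GCN encoders (Z^(l+1) = σ(D̃^(-1/2)(A+I)D̃^(-1/2) Z^(l) W^(l)))
embed the levels, Z_c = E_c(X_c, A_c), Z_g = E_g(X_g, A_g); gene embeddings
are mean-pooled per cell into Z_g* and concatenated, Z = [Z_c | Z_g*].
Inner-product decoders reconstruct the edges, A_c' = σ(Z Zᵀ) and
A_g' = σ(Z_g Z_gᵀ), and training minimizes

    L = λ_c · BCE(A_c edges, 1:1 sampled negatives)
      + λ_g · MSE(GRN diagonal blocks),          λ_c = λ_g = 1.

Held-out proximity edges scored by A_c' are the predicted CCIs; the decoded
diagonal blocks of A_g' are the refined, spatially informed per-cell GRNs.
See `docs/methods.md` for the model, the synthetic-data generator, and
numerical choices.

## Worked example

Everything below is synthetic and self-contained (no downloads): the
built-in generator plants ground-truth GRNs, CCIs and cell types, then the
model is fitted on a 70/30 edge split.

```python
import dataclasses
import spagae as s

cfg = dataclasses.replace(s.FIXTURES["easy"], seed=1)   # 200 cells x 20 genes
dataset, truth, priors, lr_db = s.simulate(cfg)
model = s.MultiLevelGAE.from_dataset(dataset, priors, lr_db,
                                     binarize_threshold=1e-8, feature_seed=1)
results = model.fit(test_fraction=0.3, seed=1)
print(results.summary())
```

```
Multi-level graph autoencoder results
=====================================================
cells: 200   genes/cell: 20   gene vertices: 4000
latent dim: 32   aggregation: mean   lambda_c: 1.0   lambda_g: 1.0
epochs: 200   lr: 0.01   seed: 1
edge split: 509 train / 218 test positive edges (test fraction 0.3, seed 1)
final losses: L_c=0.1535  L_g=0.2078  L=0.3613
test AP: 0.8870   test AUROC: 0.9026
=====================================================
```

Reading the output: 218 held-out proximity edges (plus 218 sampled
non-edges) were scored by the trained decoder; average precision 0.887 and
AUROC 0.903 mean the model ranks true spatial interactions far above random
pairs.  The final losses are the two training terms (cell-edge BCE and
gene-block MSE).  From the same results object:

```python
scores  = results.predict_cci()      # n_c x n_c CCI probability matrix
grns    = results.refined_grns()     # per-cell g x g refined GRN scores
report  = results.evaluate()         # AP / AUROC on the held-out edges
results.save("checkpoint.npz")       # weights + split, reloadable
```

A thin CLI wraps the same library for shell use:

```bash
spagae simulate --fixture easy --outdir fix --seed 1
spagae train --config cfg.yaml --test-fraction 0.3 --seed 1 --outdir run
spagae evaluate --config cfg.yaml --checkpoint run/checkpoint.npz --report rep.tsv
spagae build-graphs --config cfg.yaml --outdir graphs
```

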