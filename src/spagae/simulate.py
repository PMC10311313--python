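"""Synthetic spatial transcriptomics with known GRN and CCI ground truth.

The generator produces everything the pipeline consumes — expression,
coordinates, per-cell (corrupted) GRN priors, a ligand-receptor table — plus
the ground truth needed for evaluation: per-type GRNs, the set of cell pairs
engaged in ligand-receptor signaling, and per-cell type labels.

The expression model is a linear structural equation model rather than a
kinetic simulator: per cell type, a directed acyclic TF-to-target GRN is
sampled; root genes get type-specific lognormal levels; each downstream gene
is the weighted sum of its regulators plus Gaussian noise.  Cells within the
interaction radius whose types form a compatible pair exchange
ligand-receptor signal: the sender's ligand level is added (scaled by
``lr_effect``) to the receiver's receptor gene and, through the receptor's
outgoing GRN edges, to its targets.  Expression is clipped at zero; values
live on a continuous post-normalization-like scale.  This is rich enough to
leave recoverable spatial, CCI and GRN signal while staying transparent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import LRDatabase, SpatialExpressionDataset

__all__ = ["SimConfig", "GroundTruth", "simulate", "make_fixture", "FIXTURES"]


@dataclass
class SimConfig:
    """Conditions of a synthetic tissue.

    interaction_radius is in the units of the unit-square layout; lr_effect
    scales the additive ligand-receptor signal; grn_corruption_rate is the
    fraction of each cell's true GRN edges flipped in the supplied priors
    (emulating an imperfect upstream GRN-inference step).
    """

    n_cells: int = 200
    n_genes: int = 20
    n_cell_types: int = 3
    n_tf: int = 5
    grn_density: float = 0.25
    n_lr_pairs: int = 4
    spatial_layout: str = "clustered"  # or "uniform"
    interaction_radius: float = 0.15
    lr_effect: float = 1.0
    noise_sd: float = 0.3
    grn_corruption_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tf >= self.n_genes:
            raise ValueError("n_tf must be smaller than n_genes")
        if not 0 < self.grn_density < 1:
            raise ValueError("grn_density must be in (0, 1)")
        if not 0 <= self.grn_corruption_rate < 1:
            raise ValueError("grn_corruption_rate must be in [0, 1)")
        if self.lr_effect < 0 or self.noise_sd < 0:
            raise ValueError("lr_effect and noise_sd must be non-negative")
        if self.spatial_layout not in ("clustered", "uniform"):
            raise ValueError(f"unknown spatial_layout: {self.spatial_layout!r}")
        max_pairs = self.n_tf * (self.n_genes - self.n_tf)
        if self.n_lr_pairs > max_pairs:
            raise ValueError(f"n_lr_pairs={self.n_lr_pairs} exceeds feasible pairs ({max_pairs})")


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline tries to recover."""

    true_grns: list[np.ndarray]  # one symmetric binary g x g per cell type
    true_cci_cell_pairs: set[tuple[int, int]]
    true_lr_pairs: list[tuple[str, str]]
    cell_type_of: np.ndarray
    compatible_type_pairs: set[tuple[int, int]] = field(default_factory=set)

    def grn_of_cell(self, cell: int) -> np.ndarray:
        return self.true_grns[int(self.cell_type_of[cell])]


def _sample_type_grn(rng, g, n_tf, density):
    """Directed acyclic TF->target weights; returns (weights, symmetric binary)."""
    w = np.zeros((g, g))
    for tf in range(n_tf):
        for target in range(tf + 1, g):
            if rng.random() < density:
                sign = 1.0 if rng.random() < 0.7 else -1.0
                w[tf, target] = sign * rng.uniform(0.5, 1.5)
    binary = ((np.abs(w) + np.abs(w.T)) > 0).astype(float)
    np.fill_diagonal(binary, 0.0)
    return w, binary


def _corrupt_grn(rng, binary, rate):
    """Flip floor(rate * n_edges) edges, removals and additions balanced."""
    g = binary.shape[0]
    iu = np.triu_indices(g, k=1)
    edge_flags = binary[iu] > 0
    edges = np.where(edge_flags)[0]
    non_edges = np.where(~edge_flags)[0]
    n_flip = int(np.floor(rate * len(edges)))
    n_rem = min(n_flip // 2, len(edges))
    n_add = min(n_flip - n_rem, len(non_edges))
    out = binary.copy()
    if n_rem:
        rem = rng.choice(edges, size=n_rem, replace=False)
        out[iu[0][rem], iu[1][rem]] = 0.0
        out[iu[1][rem], iu[0][rem]] = 0.0
    if n_add:
        add = rng.choice(non_edges, size=n_add, replace=False)
        out[iu[0][add], iu[1][add]] = 1.0
        out[iu[1][add], iu[0][add]] = 1.0
    return out, n_rem + n_add


def simulate(
    config: SimConfig,
) -> tuple[SpatialExpressionDataset, GroundTruth, list[np.ndarray], LRDatabase]:
    """Generate one synthetic tissue.

    Returns the expression dataset (raw, non-negative scale), the ground
    truth, the corrupted weighted GRN priors (one per cell), and the
    ligand-receptor database.  All randomness derives from ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    g, n_c = cfg.n_genes, cfg.n_cells
    gene_names = np.array([f"g{i:03d}" for i in range(g)], dtype=object)
    cell_ids = np.array([f"cell_{i:04d}" for i in range(n_c)], dtype=object)

    # ---- cell types and layout
    cell_type = rng.integers(0, cfg.n_cell_types, size=n_c)
    if cfg.spatial_layout == "clustered":
        centroids = rng.uniform(0.15, 0.85, size=(cfg.n_cell_types, 2))
        coords = centroids[cell_type] + rng.normal(0.0, 0.08, size=(n_c, 2))
        coords = np.clip(coords, 0.0, 1.0)
    else:
        coords = rng.uniform(0.0, 1.0, size=(n_c, 2))

    # ---- per-type GRNs (DAG weights; symmetrized binary ground truth)
    weights_by_type, grn_by_type = [], []
    for _ in range(cfg.n_cell_types):
        w, b = _sample_type_grn(rng, g, cfg.n_tf, cfg.grn_density)
        if b.sum() == 0:  # guarantee a non-empty GRN per type
            tf, tgt = 0, cfg.n_tf
            w[tf, tgt] = 1.0
            b[tf, tgt] = b[tgt, tf] = 1.0
        weights_by_type.append(w)
        grn_by_type.append(b)

    # ---- ligand-receptor pairs: ligands are target genes, receptors are TFs
    targets = np.arange(cfg.n_tf, g)
    tfs = np.arange(cfg.n_tf)
    all_lr = [(int(l), int(r)) for l in targets for r in tfs]
    pick = rng.choice(len(all_lr), size=cfg.n_lr_pairs, replace=False)
    lr_idx = [all_lr[p] for p in sorted(pick)]
    lr_pairs = [(str(gene_names[l]), str(gene_names[r])) for l, r in lr_idx]

    # ---- compatible type pairs (cell-type-pair CCI semantics)
    type_pairs = [(a, b) for a in range(cfg.n_cell_types) for b in range(a, cfg.n_cell_types)]
    n_compat = max(1, len(type_pairs) // 2)
    compat_pick = rng.choice(len(type_pairs), size=n_compat, replace=False)
    compatible = {type_pairs[p] for p in sorted(compat_pick)}

    # ---- baseline expression: linear SEM in topological (index) order
    mu = rng.normal(0.5, 0.5, size=(cfg.n_cell_types, g))
    expr = np.zeros((n_c, g))
    w_all = np.stack(weights_by_type)[cell_type]  # (n_c, g, g) per-cell DAG weights
    for j in range(g):
        regulated = w_all[:, :, j]  # incoming weights for gene j, per cell
        has_reg = np.abs(regulated).sum(axis=1) > 0
        base = np.exp(mu[cell_type, j] + cfg.noise_sd * rng.standard_normal(n_c))
        contrib = np.einsum("ck,ck->c", regulated, expr)
        noise = cfg.noise_sd * rng.standard_normal(n_c)
        expr[:, j] = np.where(has_reg, contrib + noise, base)

    # ---- ligand-receptor signaling between in-radius compatible cells
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    within = d2 <= cfg.interaction_radius**2
    np.fill_diagonal(within, False)
    compat_table = np.zeros((cfg.n_cell_types, cfg.n_cell_types), dtype=bool)
    for a, b in compatible:
        compat_table[a, b] = compat_table[b, a] = True
    interacting = within & compat_table[cell_type[:, None], cell_type[None, :]]
    cci_pairs: set[tuple[int, int]] = set()
    baseline = expr.copy()
    if cfg.interaction_radius > 0 and interacting.any():
        ii, jj = np.where(np.triu(interacting, k=1))
        cci_pairs = {(int(i), int(j)) for i, j in zip(ii, jj)}
        inter_f = interacting.astype(float)
        for l, r in lr_idx:
            # summed ligand signal received by every cell from its partners
            incoming = cfg.lr_effect * (inter_f @ baseline[:, l])
            expr[:, r] += incoming
            for t in range(cfg.n_cell_types):
                cells_t = cell_type == t
                w_rec = weights_by_type[t]
                for tgt in np.where(np.abs(w_rec[r]) > 0)[0]:
                    expr[cells_t, tgt] += incoming[cells_t] * w_rec[r, tgt]

    expr = np.clip(expr, 0.0, None)

    # ---- corrupted weighted priors (imperfect upstream GRN inference)
    priors = []
    for c in range(n_c):
        corrupted, _ = _corrupt_grn(rng, grn_by_type[cell_type[c]], cfg.grn_corruption_rate)
        w = corrupted * rng.uniform(0.5, 1.5, size=corrupted.shape)
        priors.append(np.triu(w, 1) + np.triu(w, 1).T)

    dataset = SpatialExpressionDataset(
        cell_ids=cell_ids,
        gene_names=gene_names,
        expression=expr,
        coordinates=coords,
        cell_types=cell_type,
    )
    truth = GroundTruth(
        true_grns=grn_by_type,
        true_cci_cell_pairs=cci_pairs,
        true_lr_pairs=lr_pairs,
        cell_type_of=cell_type,
        compatible_type_pairs=compatible,
    )
    return dataset, truth, priors, LRDatabase(pairs=tuple(lr_pairs))


FIXTURES: dict[str, SimConfig] = {
    # oracle-scale: every matrix can be eyeballed
    "tiny": SimConfig(n_cells=12, n_genes=6, n_cell_types=2, n_tf=2,
                      grn_density=0.4, n_lr_pairs=2, interaction_radius=0.4,
                      lr_effect=1.0, noise_sd=0.2, grn_corruption_rate=0.2, seed=0),
    # the directional-acceptance conditions: strong spatial clustering,
    # moderate noise, 20% prior corruption
    "easy": SimConfig(n_cells=200, n_genes=20, n_cell_types=3, n_tf=5,
                      grn_density=0.25, n_lr_pairs=4, interaction_radius=0.15,
                      lr_effect=1.0, noise_sd=0.3, grn_corruption_rate=0.2, seed=0),
    # mirrors the seqFISH mouse-visual-cortex panel shape (125 genes, 1597 cells)
    "realscale": SimConfig(n_cells=1597, n_genes=125, n_cell_types=5, n_tf=15,
                           grn_density=0.1, n_lr_pairs=10, interaction_radius=0.08,
                           lr_effect=1.0, noise_sd=0.3, grn_corruption_rate=0.2, seed=0),
}


def make_fixture(name: str, outdir: str | Path, seed: int | None = None) -> dict:
    """Write a named fixture bundle to disk; returns the manifest dict.

    Emits expression.tsv, coords.tsv, lr_pairs.tsv, per-cell grn_prior_*.tsv
    (a single stacked grn_priors.tsv for ``realscale``), truth/*.tsv and
    manifest.json.
    """
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")
    cfg = FIXTURES[name]
    if seed is not None:
        cfg = SimConfig(**{**asdict(cfg), "seed": seed})
    dataset, truth, priors, lr_db = simulate(cfg)
    outdir = Path(outdir)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)

    pd.DataFrame(dataset.expression, index=dataset.cell_ids,
                 columns=dataset.gene_names).to_csv(outdir / "expression.tsv", sep="\t")
    pd.DataFrame({"cell_id": dataset.cell_ids,
                  "x": dataset.coordinates[:, 0],
                  "y": dataset.coordinates[:, 1]}).to_csv(
        outdir / "coords.tsv", sep="\t", index=False)
    with open(outdir / "lr_pairs.tsv", "w") as fh:
        fh.write("ligand\treceptor\n")
        for l, r in lr_db:
            fh.write(f"{l}\t{r}\n")

    if name == "realscale":
        stacked = np.vstack(priors)
        pd.DataFrame(stacked).to_csv(outdir / "grn_priors.tsv", sep="\t",
                                     index=False, header=False, float_format="%.6g")
        prior_layout = "stacked"
    else:
        width = len(str(len(priors) - 1))
        for c, p in enumerate(priors):
            pd.DataFrame(p).to_csv(outdir / f"grn_prior_{c:0{width}d}.tsv", sep="\t",
                                   index=False, header=False, float_format="%.6g")
        prior_layout = "per_cell"

    for t, grn in enumerate(truth.true_grns):
        pd.DataFrame(grn).to_csv(outdir / "truth" / f"grn_type_{t}.tsv", sep="\t",
                                 index=False, header=False, float_format="%.6g")
    pd.DataFrame({"cell_id": dataset.cell_ids,
                  "cell_type": truth.cell_type_of}).to_csv(
        outdir / "truth" / "cell_types.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(truth.true_cci_cell_pairs),
                 columns=["cell_i", "cell_j"]).to_csv(
        outdir / "truth" / "cci_pairs.tsv", sep="\t", index=False)

    manifest = {"fixture": name, "config": asdict(cfg), "prior_layout": prior_layout,
                "n_cci_pairs": len(truth.true_cci_cell_pairs)}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
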