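"""Training objective and edge-splitting protocol.

The model is optimized on two tasks: reconstructing the cell-level proximity
edges (binary cross-entropy on positive edges and 1:1 uniformly sampled
negative non-edges) and keeping the reconstructed gene-level diagonal blocks
close to the input per-cell GRNs (mean squared error restricted to the
block-diagonal mask).  The total loss is the weighted sum

    L = lambda_c * L_c + lambda_g * L_g,       lambda_c = lambda_g = 1 by default.

A held-out fraction of proximity edges (30% by default) is removed from the
training graph and used, together with matched negatives, to score link
prediction.  The noise-robustness protocol perturbs the training edge list
with false-positive and false-negative edges at a given rate of the original
edge count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .gae import sigmoid

__all__ = [
    "EdgeSplit",
    "TrainConfig",
    "MaskSpec",
    "split_edges",
    "training_adjacency",
    "cell_loss",
    "cell_loss_all_pairs",
    "build_block_mask",
    "gene_loss",
    "total_loss",
    "perturb_training_edges",
]


def _canon(pairs: np.ndarray) -> np.ndarray:
    """Canonicalize an (m, 2) pair array to i < j rows."""
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    return np.column_stack([pairs.min(axis=1), pairs.max(axis=1)])


def _pair_set(pairs: np.ndarray) -> set[tuple[int, int]]:
    return {(int(i), int(j)) for i, j in _canon(pairs)}


@dataclass
class EdgeSplit:
    """Train/test partition of proximity edges with 1:1 negative samples."""

    train_pos: np.ndarray
    test_pos: np.ndarray
    train_neg: np.ndarray
    test_neg: np.ndarray
    n_cells: int
    test_fraction: float
    seed: int

    def describe(self) -> str:
        return (
            f"{len(self.train_pos)} train / {len(self.test_pos)} test positive edges "
            f"(test fraction {self.test_fraction}, seed {self.seed})"
        )

    def test_pairs_labels(self) -> tuple[np.ndarray, np.ndarray]:
        pairs = np.vstack([self.test_pos, self.test_neg])
        labels = np.concatenate(
            [np.ones(len(self.test_pos)), np.zeros(len(self.test_neg))]
        )
        return pairs, labels

    def train_pairs_labels(
        self, train_pos: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        pos = self.train_pos if train_pos is None else train_pos
        pairs = np.vstack([pos, self.train_neg])
        labels = np.concatenate([np.ones(len(pos)), np.zeros(len(self.train_neg))])
        return pairs, labels


def split_edges(a_c: sp.spmatrix | np.ndarray, test_fraction: float, seed: int) -> EdgeSplit:
    """Uniform random train/test partition of the unique undirected edges.

    Negative (non-edge) pairs are sampled uniformly without replacement,
    excluding self-pairs, in a 1:1 ratio with the positives of each
    partition; train and test negatives are disjoint.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    a = sp.csr_matrix(a_c)
    n = a.shape[0]
    coo = sp.triu(a, k=1).tocoo()
    edges = np.column_stack([coo.row, coo.col]).astype(np.int64)
    edges = edges[np.lexsort((edges[:, 1], edges[:, 0]))]
    m = len(edges)
    if m < 2:
        raise ValueError("graph needs at least 2 edges to split")
    n_test = int(round(test_fraction * m))
    n_test = min(max(n_test, 1), m - 1)

    rng = np.random.default_rng(seed)
    perm = rng.permutation(m)
    test_pos = edges[perm[:n_test]]
    train_pos = edges[perm[n_test:]]

    n_non_edges = n * (n - 1) // 2 - m
    if n_non_edges < m:
        raise ValueError(
            f"cannot sample {m} negative pairs: only {n_non_edges} non-edges exist"
        )
    edge_set = _pair_set(edges)
    negatives: list[tuple[int, int]] = []
    chosen: set[tuple[int, int]] = set()
    if n <= 2000 and n_non_edges < 5_000_000:
        iu = np.triu_indices(n, k=1)
        all_pairs = np.column_stack(iu)
        dense = np.asarray(a.todense()) > 0
        mask = ~dense[iu]
        candidates = all_pairs[mask]
        pick = rng.choice(len(candidates), size=m, replace=False)
        negatives = [tuple(map(int, candidates[p])) for p in pick]
    else:
        while len(negatives) < m:
            ii = rng.integers(0, n, size=2 * (m - len(negatives)))
            jj = rng.integers(0, n, size=len(ii))
            for i, j in zip(ii, jj):
                if i == j:
                    continue
                pair = (int(min(i, j)), int(max(i, j)))
                if pair in edge_set or pair in chosen:
                    continue
                chosen.add(pair)
                negatives.append(pair)
                if len(negatives) == m:
                    break
    neg = np.array(negatives, dtype=np.int64)
    test_neg = neg[:n_test]
    train_neg = neg[n_test:]
    return EdgeSplit(
        train_pos=train_pos,
        test_pos=test_pos,
        train_neg=train_neg,
        test_neg=test_neg,
        n_cells=n,
        test_fraction=test_fraction,
        seed=seed,
    )


def training_adjacency(
    n_cells: int, train_pos: np.ndarray
) -> sp.csr_matrix:
    """Symmetric binary adjacency holding only the training positive edges."""
    train_pos = _canon(train_pos)
    data = np.ones(len(train_pos))
    a = sp.coo_matrix(
        (data, (train_pos[:, 0], train_pos[:, 1])), shape=(n_cells, n_cells)
    ).tocsr()
    a = a.maximum(a.T)
    a.data[:] = 1.0
    return a


def cell_loss(scores: np.ndarray, labels: np.ndarray, eps: float = 1e-12) -> float:
    """Mean binary cross-entropy over an evaluated pair set.

    Scores are clipped to [eps, 1 - eps] against logistic saturation.
    """
    scores = np.clip(np.asarray(scores, dtype=float), eps, 1.0 - eps)
    labels = np.asarray(labels, dtype=float)
    if scores.size == 0:
        raise ValueError("empty pair set")
    return float(
        -np.mean(labels * np.log(scores) + (1.0 - labels) * np.log(1.0 - scores))
    )


def cell_loss_all_pairs(
    a_c: np.ndarray | sp.spmatrix, a_c_prime: np.ndarray, eps: float = 1e-12
) -> float:
    """All-pairs BCE with the 1/n_c^2 normalization (includes the diagonal)."""
    a = np.asarray(a_c.todense() if sp.issparse(a_c) else a_c, dtype=float)
    p = np.clip(np.asarray(a_c_prime, dtype=float), eps, 1.0 - eps)
    return float(-np.mean(a * np.log(p) + (1.0 - a) * np.log(1.0 - p)))


@dataclass
class MaskSpec:
    """The block-diagonal mask: 1s in the g x g blocks along the diagonal."""

    n_cells: int
    g: int

    @property
    def n_entries(self) -> int:
        return self.n_cells * self.g**2

    def indices(self) -> tuple[np.ndarray, np.ndarray]:
        """All (u, v) with floor(u/g) == floor(v/g)."""
        offsets = np.arange(self.g)
        base = np.arange(self.n_cells) * self.g
        u = np.repeat(base, self.g**2) + np.tile(np.repeat(offsets, self.g), self.n_cells)
        v = np.repeat(base, self.g**2) + np.tile(np.tile(offsets, self.g), self.n_cells)
        return u, v

    def contains(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        return np.asarray(u) // self.g == np.asarray(v) // self.g

    def apply(self, matrix: np.ndarray | sp.spmatrix) -> sp.csr_matrix:
        """Zero every off-block entry (idempotent)."""
        coo = sp.coo_matrix(matrix)
        keep = self.contains(coo.row, coo.col)
        return sp.csr_matrix(
            (coo.data[keep], (coo.row[keep], coo.col[keep])), shape=coo.shape
        )


def build_block_mask(n_cells: int, g: int) -> MaskSpec:
    if n_cells <= 0 or g <= 0:
        raise ValueError("n_cells and g must be positive")
    return MaskSpec(n_cells=n_cells, g=g)


def gene_loss(
    a_g: sp.spmatrix | np.ndarray,
    z_g: np.ndarray,
    mask: MaskSpec,
    self_loops: bool = True,
) -> float:
    """Masked MSE between input GRN blocks and their reconstruction.

    Computed blockwise from the gene embeddings: block i of the
    reconstruction is logistic(B_i B_i^T) for B_i the g rows of Z_g in cell
    i.  The full n_g x n_g reconstruction is never materialized.

    With ``self_loops`` (the default) the target blocks are A + I: the
    inner-product decoder scores every self-pair at logistic(|z_u|^2) >= 1/2,
    so a zero-diagonal target makes the collapsed embedding Z_g = 0 a local
    attractor; treating self-edges as positives (the usual graph-autoencoder
    convention) removes that degeneracy.
    """
    z_g = np.asarray(z_g, dtype=float)
    n_c, g = mask.n_cells, mask.g
    if z_g.shape[0] != n_c * g:
        raise ValueError(f"Z_g has {z_g.shape[0]} rows, mask implies {n_c * g}")
    zb = z_g.reshape(n_c, g, -1)
    pred = sigmoid(np.einsum("cgd,chd->cgh", zb, zb))
    target = _stack_blocks(a_g, n_c, g)
    if self_loops:
        target = target + np.eye(g)[None, :, :]
    return float(np.sum((pred - target) ** 2) / mask.n_entries)


def _stack_blocks(a_g: sp.spmatrix | np.ndarray, n_c: int, g: int) -> np.ndarray:
    """Dense (n_c, g, g) stack of the diagonal blocks of A_g."""
    if sp.issparse(a_g):
        a_g = sp.csr_matrix(a_g)
        out = np.empty((n_c, g, g))
        for c in range(n_c):
            lo, hi = c * g, (c + 1) * g
            out[c] = np.asarray(a_g[lo:hi, lo:hi].todense())
        return out
    a_g = np.asarray(a_g, dtype=float)
    out = np.empty((n_c, g, g))
    for c in range(n_c):
        lo, hi = c * g, (c + 1) * g
        out[c] = a_g[lo:hi, lo:hi]
    return out


@dataclass
class TrainConfig:
    """Hyperparameters of the optimization.

    lambda_c and lambda_g weight the cell-level BCE and the gene-level masked
    MSE; both default to 1.  The architecture defaults to two GCN layers per
    encoder (hidden 64, latent 32, ReLU between layers, identity on the last).
    """

    lambda_c: float = 1.0
    lambda_g: float = 1.0
    epochs: int = 200
    eval_every: int = 10
    learning_rate: float = 0.01
    seed: int = 0
    aggregation: str = "mean"  # or "concat"
    hidden_dim: int = 64
    latent_dim: int = 32
    activation: str = "relu"
    loss_mode: str = "sampled"  # or "all_pairs"
    zero_gene_in_combined: bool = False  # diagnostic: degenerate to single-level GAE

    def __post_init__(self) -> None:
        if self.lambda_c < 0 or self.lambda_g < 0:
            raise ValueError("loss weights must be non-negative")
        if self.aggregation not in ("mean", "concat"):
            raise ValueError(f"unknown aggregation: {self.aggregation!r}")
        if self.loss_mode not in ("sampled", "all_pairs"):
            raise ValueError(f"unknown loss mode: {self.loss_mode!r}")

    def replace(self, **kwargs) -> "TrainConfig":
        return replace(self, **kwargs)


def total_loss(l_c: float, l_g: float, config: TrainConfig) -> float:
    """Weighted sum lambda_c * L_c + lambda_g * L_g."""
    return config.lambda_c * l_c + config.lambda_g * l_g


def perturb_training_edges(
    train_pos: np.ndarray,
    fp_rate: float,
    fn_rate: float,
    candidate_non_edges: np.ndarray,
    seed: int,
) -> np.ndarray:
    """Corrupt the training edge list with false positives / false negatives.

    Adds floor(fp_rate * m) uniformly sampled candidate non-edges and removes
    floor(fn_rate * m) uniformly sampled true edges, m being the original
    training edge count.  The test set is untouched by construction.
    """
    if not (0 <= fp_rate <= 1 and 0 <= fn_rate <= 1):
        raise ValueError("perturbation rates must be within [0, 1]")
    train_pos = _canon(train_pos)
    candidates = _canon(candidate_non_edges) if len(candidate_non_edges) else np.empty((0, 2), int)
    m = len(train_pos)
    n_add = int(np.floor(fp_rate * m))
    n_del = int(np.floor(fn_rate * m))
    if n_add > len(candidates):
        raise ValueError(
            f"need {n_add} candidate non-edges for fp perturbation, have {len(candidates)}"
        )
    rng = np.random.default_rng(seed)
    keep_idx = rng.choice(m, size=m - n_del, replace=False) if n_del else np.arange(m)
    kept = train_pos[np.sort(keep_idx)]
    if n_add:
        add_idx = rng.choice(len(candidates), size=n_add, replace=False)
        kept = np.vstack([kept, candidates[np.sort(add_idx)]])
    return kept
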