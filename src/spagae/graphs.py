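"""Construction of the two-level input graphs.

The cell level is a spatial proximity graph: cells are vertices, edges come
from a k-nearest-neighbour search on the 2D coordinates, symmetrized by
union (an edge exists if either endpoint ranks the other among its k nearest).

The gene level stacks every cell's binarized GRN into one block-diagonal
adjacency over n_cells * g gene vertices, then augments it with cross-cell
ligand-receptor edges: for every pair of spatially adjacent cells and every
ligand-receptor pair present in the gene panel, the ligand vertex of one cell
is connected to the receptor vertex of the other, in both directions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .io import LRDatabase, SpatialExpressionDataset

__all__ = [
    "CellGraph",
    "GeneGraph",
    "GRNPrior",
    "build_cell_graph",
    "binarize_grn_priors",
    "identify_lr_vertices",
    "assemble_gene_graph",
]

DEFAULT_K = 6  # 2D packing-typical neighbour count; satisfies the k >= 3 assumption


@dataclass
class CellGraph:
    """Binary symmetric proximity adjacency plus per-cell expression features."""

    adjacency: sp.csr_matrix  # n_c x n_c, binary, zero diagonal
    features: np.ndarray  # n_c x f_c preprocessed expression
    k: int = 0

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]

    def edge_array(self) -> np.ndarray:
        """Unique undirected edges as an (m, 2) array with i < j."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        edges = np.column_stack([coo.row, coo.col]).astype(np.int64)
        order = np.lexsort((edges[:, 1], edges[:, 0]))
        return edges[order]


@dataclass
class GeneGraph:
    """Block-diagonal per-cell GRNs plus cross-cell ligand-receptor edges.

    Gene vertex ``v`` belongs to cell ``v // g`` and carries gene
    ``gene_names[v % g]``.
    """

    adjacency: sp.csr_matrix  # n_g x n_g binary symmetric
    gene_names: np.ndarray
    n_cells: int
    features: np.ndarray | None = None  # n_g x f_g, filled by features module
    ligand_idx: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    receptor_idx: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    # (ligand gene index, receptor gene index) pairs realized in the panel
    lr_pair_idx: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))

    @property
    def g(self) -> int:
        return len(self.gene_names)

    @property
    def n_vertices(self) -> int:
        return self.adjacency.shape[0]

    @property
    def cell_of(self) -> np.ndarray:
        return np.arange(self.n_vertices) // self.g

    def gene_of(self, vertex: int) -> str:
        return str(self.gene_names[vertex % self.g])

    def lr_vertices(self, cell: int) -> tuple[np.ndarray, np.ndarray]:
        """Vertex indices of ligand and receptor genes inside one cell's block."""
        base = cell * self.g
        return base + self.ligand_idx, base + self.receptor_idx

    def block(self, cell: int) -> np.ndarray:
        """Dense g x g adjacency block of one cell."""
        lo, hi = cell * self.g, (cell + 1) * self.g
        return np.asarray(self.adjacency[lo:hi, lo:hi].todense())

    def block_diagonal_only(self) -> sp.csr_matrix:
        """The adjacency with all cross-cell (off-block) edges removed."""
        coo = self.adjacency.tocoo()
        keep = (coo.row // self.g) == (coo.col // self.g)
        return sp.csr_matrix(
            (coo.data[keep], (coo.row[keep], coo.col[keep])), shape=coo.shape
        )

    def with_cell_adjacency(self, cell_adjacency: sp.spmatrix) -> sp.csr_matrix:
        """Rebuild the gene adjacency with cross edges from another cell graph.

        The GRN blocks are kept as-is; ligand-receptor cross edges are
        re-derived from ``cell_adjacency`` (e.g. a training-only proximity
        graph, so held-out cell edges never leak into gene-level propagation).
        """
        g, n_g = self.g, self.n_vertices
        blocks = self.block_diagonal_only().tocoo()
        rows, cols = [blocks.row], [blocks.col]
        if len(self.lr_pair_idx):
            cell_edges = sp.triu(sp.csr_matrix(cell_adjacency), k=1).tocoo()
            for ci, cj in zip(cell_edges.row, cell_edges.col):
                for l, r in self.lr_pair_idx:
                    rows.append(np.array([ci * g + l, cj * g + l]))
                    cols.append(np.array([cj * g + r, ci * g + r]))
        rr, cc = np.concatenate(rows), np.concatenate(cols)
        adj = sp.coo_matrix((np.ones(len(rr)), (rr, cc)), shape=(n_g, n_g)).tocsr()
        adj = adj.maximum(adj.T)
        adj.data[:] = 1.0
        adj.setdiag(0)
        adj.eliminate_zeros()
        return adj


@dataclass
class GRNPrior:
    """A weighted per-cell GRN and its binarized adjacency."""

    weighted: np.ndarray
    binary: np.ndarray
    threshold_used: float


def build_cell_graph(dataset: SpatialExpressionDataset, k: int = DEFAULT_K) -> CellGraph:
    """kNN proximity graph on the spatial coordinates, union-symmetrized.

    Distance ties (including duplicate coordinates) break toward the lower
    cell index; the self-distance is excluded.
    """
    coords = dataset.coordinates
    n_c = coords.shape[0]
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= n_c:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n_c})")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates contain non-finite values")
    # Full distance matrix + stable argsort: deterministic tie-breaks by index.
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, -1.0)  # pin self first even under duplicate coordinates
    order = np.argsort(d2, axis=1, kind="stable")
    neigh = order[:, 1 : k + 1]
    rows = np.repeat(np.arange(n_c), k)
    cols = neigh.ravel()
    adj = sp.coo_matrix((np.ones(n_c * k), (rows, cols)), shape=(n_c, n_c)).tocsr()
    adj = adj.maximum(adj.T)  # union symmetrization
    adj.data[:] = 1.0
    adj.setdiag(0)
    adj.eliminate_zeros()
    return CellGraph(adjacency=adj, features=np.asarray(dataset.expression, float), k=k)


def _symmetrize_abs(w: np.ndarray) -> np.ndarray:
    a = np.abs(np.asarray(w, dtype=float))
    out = np.maximum(a, a.T)
    np.fill_diagonal(out, 0.0)
    return out


def binarize_grn_priors(
    weighted: list[np.ndarray],
    rule: str = "absolute",
    threshold: float | None = None,
    q: float | None = None,
) -> list[GRNPrior]:
    """Convert weighted GRN matrices to binary adjacencies.

    Matrices are first symmetrized by max(|w_ij|, |w_ji|) with a zero
    diagonal.  ``rule="absolute"`` keeps pairs with weight >= ``threshold``;
    if ``threshold`` is None it defaults, per cell, to the 90th percentile of
    the off-diagonal weights.  ``rule="top_q"`` keeps the floor(q * n_pairs)
    largest pairs.
    """
    out: list[GRNPrior] = []
    for w in weighted:
        w = np.asarray(w, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"GRN prior is not square: {w.shape}")
        if not np.all(np.isfinite(w)):
            raise ValueError("GRN prior contains non-finite weights")
        sym = _symmetrize_abs(w)
        g = sym.shape[0]
        iu = np.triu_indices(g, k=1)
        vals = sym[iu]
        if rule == "absolute":
            t = threshold
            if t is None:
                t = float(np.quantile(vals, 0.9)) if vals.size else 0.0
            binary = (sym >= t).astype(float) if t > 0 else (sym > 0).astype(float)
        elif rule == "top_q":
            if q is None:
                raise ValueError("rule 'top_q' requires q")
            m = int(math.floor(q * vals.size))
            binary = np.zeros_like(sym)
            t = math.inf
            if m > 0:
                order = np.argsort(-vals, kind="stable")[:m]
                t = float(vals[order[-1]])
                binary[(iu[0][order], iu[1][order])] = 1.0
                binary = np.maximum(binary, binary.T)
        else:
            raise ValueError(f"unknown binarization rule: {rule!r}")
        np.fill_diagonal(binary, 0.0)
        out.append(GRNPrior(weighted=w, binary=binary, threshold_used=float(t)))
    return out


def identify_lr_vertices(
    gene_names: np.ndarray | list[str], lr_db: LRDatabase
) -> tuple[set[int], set[int]]:
    """Gene-panel indices that appear as ligands / as receptors in the database."""
    index = {str(name): i for i, name in enumerate(gene_names)}
    ligands = {index[l] for l, _ in lr_db if l in index}
    receptors = {index[r] for _, r in lr_db if r in index}
    return ligands, receptors


def _as_binary_blocks(binary_grns) -> list[np.ndarray]:
    blocks = []
    for b in binary_grns:
        blocks.append(b.binary if isinstance(b, GRNPrior) else np.asarray(b, float))
    return blocks


def assemble_gene_graph(
    cell_graph: CellGraph,
    binary_grns: list,
    gene_names: np.ndarray | list[str],
    lr_db: LRDatabase,
    cell_adjacency: sp.spmatrix | None = None,
) -> GeneGraph:
    """Stack per-cell GRNs block-diagonally and add ligand-receptor cross edges.

    For every adjacent cell pair (i, j) and every (ligand L, receptor R) pair
    with both genes in the panel, undirected edges (L@i, R@j) and (L@j, R@i)
    are added.  ``cell_adjacency`` overrides the proximity adjacency used for
    cross edges (e.g. a training-only adjacency); GRN blocks are unaffected.
    """
    blocks = _as_binary_blocks(binary_grns)
    n_c = cell_graph.n_cells
    if len(blocks) != n_c:
        raise ValueError(f"got {len(blocks)} GRNs for {n_c} cells")
    gene_names = np.asarray(gene_names, dtype=object)
    g = len(gene_names)
    for i, b in enumerate(blocks):
        if b.shape != (g, g):
            raise ValueError(f"GRN {i} has shape {b.shape}, expected ({g}, {g})")

    a_c = cell_graph.adjacency if cell_adjacency is None else sp.csr_matrix(cell_adjacency)
    adj = sp.block_diag([sp.csr_matrix(b) for b in blocks], format="coo")

    name_index = {str(name): i for i, name in enumerate(gene_names)}
    lr_idx = [
        (name_index[l], name_index[r])
        for l, r in lr_db
        if l in name_index and r in name_index
    ]
    rows = [adj.row]
    cols = [adj.col]
    if lr_idx:
        cell_edges = sp.triu(a_c, k=1).tocoo()
        for ci, cj in zip(cell_edges.row, cell_edges.col):
            for l, r in lr_idx:
                rows.append(np.array([ci * g + l, cj * g + l]))
                cols.append(np.array([cj * g + r, ci * g + r]))
    n_g = n_c * g
    data = np.ones(sum(len(r) for r in rows))
    full = sp.coo_matrix(
        (data, (np.concatenate(rows), np.concatenate(cols))), shape=(n_g, n_g)
    ).tocsr()
    full = full.maximum(full.T)
    full.data[:] = 1.0
    full.setdiag(0)
    full.eliminate_zeros()

    ligands, receptors = identify_lr_vertices(gene_names, lr_db)
    return GeneGraph(
        adjacency=full,
        gene_names=gene_names,
        n_cells=n_c,
        ligand_idx=np.array(sorted(ligands), dtype=int),
        receptor_idx=np.array(sorted(receptors), dtype=int),
        lr_pair_idx=np.array(lr_idx, dtype=int).reshape(-1, 2),
    )
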