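"""Initial gene-vertex features from random-walk neighbourhood embeddings.

Each gene vertex receives a feature vector describing its local network
neighbourhood, in the node2vec spirit: seeded (optionally biased) random
walks are generated on the graph, windowed co-occurrence counts are collected
from the walks, and the positive pointwise-mutual-information (PPMI) matrix of
those counts is factorized by truncated SVD.  This walk-plus-factorization
route gives deterministic embeddings for a fixed seed, which the rest of the
pipeline relies on.

By default the walks run on the block-diagonal (GRN-only) adjacency, so that
walks stay inside each cell's regulatory component and the features describe
purely intracellular neighbourhoods; set ``scope="full"`` to include the
cross-cell ligand-receptor edges.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import svds

from .graphs import GeneGraph

__all__ = ["generate_walks", "walk_embedding", "compute_gene_features"]


def generate_walks(
    adjacency: sp.spmatrix,
    n_walks: int = 10,
    walk_length: int = 80,
    p: float = 1.0,
    q: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Second-order random walks from every non-isolated vertex.

    Returns an (n_starts * n_walks, walk_length) int array of vertex indices.
    ``p`` and ``q`` are the return and in-out bias parameters; with
    p = q = 1 the walk is a plain first-order random walk and is generated
    fully vectorized.  Isolated vertices produce no walks.
    """
    if walk_length < 2:
        raise ValueError("walk_length must be at least 2")
    adj = sp.csr_matrix(adjacency)
    n = adj.shape[0]
    deg = np.diff(adj.indptr)
    starts = np.repeat(np.where(deg > 0)[0], n_walks)
    rng = np.random.default_rng(seed)
    if len(starts) == 0:
        return np.empty((0, walk_length), dtype=np.int64)

    if p == 1.0 and q == 1.0:
        walks = np.empty((len(starts), walk_length), dtype=np.int64)
        walks[:, 0] = starts
        cur = starts.copy()
        for step in range(1, walk_length):
            r = rng.random(len(cur))
            offs = np.floor(r * deg[cur]).astype(np.int64)
            cur = adj.indices[adj.indptr[cur] + offs]
            walks[:, step] = cur
        return walks

    neigh = [adj.indices[adj.indptr[v] : adj.indptr[v + 1]] for v in range(n)]
    neigh_sets = [set(nv.tolist()) for nv in neigh]
    walks = np.empty((len(starts), walk_length), dtype=np.int64)
    for w, s in enumerate(starts):
        walk = [s, int(neigh[s][rng.integers(len(neigh[s]))])]
        while len(walk) < walk_length:
            prev, cur = walk[-2], walk[-1]
            nbrs = neigh[cur]
            weights = np.where(
                nbrs == prev,
                1.0 / p,
                np.where([x in neigh_sets[prev] for x in nbrs], 1.0, 1.0 / q),
            )
            weights = weights / weights.sum()
            walk.append(int(rng.choice(nbrs, p=weights)))
        walks[w] = walk
    return walks


def _factorize_symmetric(mat: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    u, s, _ = np.linalg.svd(mat)
    return u[:, :k], s[:k]


def walk_embedding(
    walks: np.ndarray,
    n_vertices: int,
    dim: int,
    window: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Embed vertices by factorizing the walks' PPMI co-occurrence matrix.

    Windowed co-occurrence counts are turned into positive pointwise mutual
    information, and each connected component of the co-occurrence graph is
    factorized separately (walks never cross components, so the PPMI matrix
    is block-structured; a single global truncation would discard most of the
    per-component spectrum when there are many components).  Rows are
    U * sqrt(S) of the component's PPMI, padded with zero columns beyond the
    component's rank.  Vertices that never occur in a walk get zero rows.
    """
    if dim < 2:
        raise ValueError("embedding dimension must be at least 2")
    out = np.zeros((n_vertices, dim))
    if walks.size == 0:
        return out
    counts = sp.csr_matrix((n_vertices, n_vertices))
    chunk = max(1, 2_000_000 // max(walks.shape[1], 1))
    for lo in range(0, walks.shape[0], chunk):
        part = walks[lo : lo + chunk]
        rows, cols = [], []
        for offset in range(1, window + 1):
            if part.shape[1] <= offset:
                break
            a = part[:, :-offset].ravel()
            b = part[:, offset:].ravel()
            rows.extend([a, b])
            cols.extend([b, a])
        rr = np.concatenate(rows)
        cc = np.concatenate(cols)
        counts = counts + sp.coo_matrix(
            (np.ones(len(rr)), (rr, cc)), shape=(n_vertices, n_vertices)
        ).tocsr()

    total = counts.sum()
    row_sums = np.asarray(counts.sum(axis=1)).ravel()
    coo = counts.tocoo()
    with np.errstate(divide="ignore"):
        pmi = np.log(coo.data * total / (row_sums[coo.row] * row_sums[coo.col]))
    keep = pmi > 0
    ppmi = sp.coo_matrix(
        (pmi[keep], (coo.row[keep], coo.col[keep])), shape=counts.shape
    ).tocsr()
    if ppmi.nnz == 0:
        return out

    from scipy.sparse.csgraph import connected_components

    rng = np.random.default_rng(seed)
    _, labels = connected_components(counts, directed=False)
    for comp in np.unique(labels[np.asarray(counts.sum(axis=1)).ravel() > 0]):
        idx = np.where(labels == comp)[0]
        if len(idx) < 2:
            continue
        k = min(dim, len(idx))
        if len(idx) <= 512:
            sub = np.asarray(ppmi[np.ix_(idx, idx)].todense())
            u, s = _factorize_symmetric(sub, k)
        else:
            k = min(k, len(idx) - 1)
            v0 = rng.standard_normal(len(idx))
            u, s, _ = svds(ppmi[np.ix_(idx, idx)].tocsc(), k=k, v0=v0)
            order = np.argsort(-s)
            u, s = u[:, order], s[order]
        # deterministic sign convention: largest-magnitude loading positive
        flip = np.sign(u[np.argmax(np.abs(u), axis=0), np.arange(u.shape[1])])
        flip[flip == 0] = 1.0
        out[idx, : u.shape[1]] = u * flip * np.sqrt(np.maximum(s, 0.0))
    return out


def compute_gene_features(
    gene_graph: GeneGraph,
    dim: int = 32,
    n_walks: int = 10,
    walk_length: int = 80,
    window: int = 5,
    p: float = 1.0,
    q: float = 1.0,
    seed: int = 0,
    scope: str = "blocks",
) -> np.ndarray:
    """Fill ``gene_graph.features`` with walk-based neighbourhood embeddings.

    ``scope="blocks"`` (default) walks on the GRN blocks only, keeping each
    cell's component disjoint; ``scope="full"`` walks on the assembled
    adjacency including ligand-receptor cross edges.
    """
    if scope == "blocks":
        adj = gene_graph.block_diagonal_only()
    elif scope == "full":
        adj = gene_graph.adjacency
    else:
        raise ValueError(f"unknown scope: {scope!r}")
    walks = generate_walks(
        adj, n_walks=n_walks, walk_length=walk_length, p=p, q=q, seed=seed
    )
    features = walk_embedding(
        walks, n_vertices=gene_graph.n_vertices, dim=dim, window=window, seed=seed
    )
    gene_graph.features = features
    return features
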