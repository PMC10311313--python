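"""Multi-level graph autoencoder: layers, encoders, aggregation, decoders.

The encoder is a stack of graph-convolution layers with the symmetric
normalization

    Z^(l+1) = sigma( D~^(-1/2) (A + I) D~^(-1/2)  Z^(l)  W^(l) ),

where D~ is the degree matrix of A + I.  Two parallel stacks (no parameter
sharing) embed the cell-level and the gene-level graph; gene embeddings are
aggregated per cell (mean pooling by default, concatenation optionally) and
concatenated with the cell embeddings into the combined representation
Z = [Z_c | Z_g*].  Both decoders are inner-product decoders: the probability
of an edge (u, v) is the logistic function of <z_u, z_v>.  The interlayer
activation and the decoder squashing are both written sigma in the field's
notation; here they are separate configurables (ReLU between layers, identity
on the final layer, logistic in the decoders).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "normalize_adjacency",
    "sigmoid",
    "GCNLayerParams",
    "EncoderParams",
    "EmbeddingSet",
    "gcn_forward",
    "encode",
    "aggregate_gene_embeddings",
    "combine_embeddings",
    "decode_cell",
    "decode_gene",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def identity(x: np.ndarray) -> np.ndarray:
    return x


ACTIVATIONS = {"relu": relu, "identity": identity, "sigmoid": sigmoid}


def normalize_adjacency(adjacency: np.ndarray | sp.spmatrix) -> sp.csr_matrix | np.ndarray:
    """Symmetrically normalized propagation matrix D~^(-1/2)(A + I)D~^(-1/2).

    ``adjacency`` must be square, symmetric and hollow (zero diagonal).  The
    result is symmetric but not row-stochastic.  Sparse in, sparse out.
    """
    sparse_in = sp.issparse(adjacency)
    a = sp.csr_matrix(adjacency) if sparse_in else np.asarray(adjacency, dtype=float)
    n = a.shape[0]
    if a.shape[0] != a.shape[1]:
        raise ValueError(f"adjacency is not square: {a.shape}")
    asym = abs(a - a.T)
    max_asym = asym.max() if not sparse_in else (asym.max() if asym.nnz else 0.0)
    if max_asym > 1e-12:
        raise ValueError("adjacency must be symmetric")
    if sparse_in:
        a_tilde = (a + sp.identity(n, format="csr")).tocsr()
        deg = np.asarray(a_tilde.sum(axis=1)).ravel()
        inv_sqrt = 1.0 / np.sqrt(deg)
        d = sp.diags(inv_sqrt)
        return (d @ a_tilde @ d).tocsr()
    a_tilde = a + np.eye(n)
    inv_sqrt = 1.0 / np.sqrt(a_tilde.sum(axis=1))
    return a_tilde * inv_sqrt[:, None] * inv_sqrt[None, :]


@dataclass
class GCNLayerParams:
    """One graph-convolution layer: a weight matrix and an elementwise activation."""

    weight: np.ndarray
    activation: str = "relu"

    def __post_init__(self) -> None:
        self.weight = np.asarray(self.weight, dtype=float)
        if not np.all(np.isfinite(self.weight)):
            raise ValueError("layer weights must be finite")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation: {self.activation!r}")


@dataclass
class EncoderParams:
    """Two parallel GCN stacks; the last layer of each outputs the latent dim."""

    cell_layers: list[GCNLayerParams]
    gene_layers: list[GCNLayerParams]

    def __post_init__(self) -> None:
        for name, stack in (("cell", self.cell_layers), ("gene", self.gene_layers)):
            for prev, nxt in zip(stack, stack[1:]):
                if prev.weight.shape[1] != nxt.weight.shape[0]:
                    raise ValueError(f"{name} stack has inconsistent layer dims")
        if self.cell_layers and self.gene_layers:
            if self.cell_layers[-1].weight.shape[1] != self.gene_layers[-1].weight.shape[1]:
                raise ValueError("cell and gene stacks must share the latent dimension")

    @property
    def latent_dim(self) -> int:
        return self.cell_layers[-1].weight.shape[1]


@dataclass
class EmbeddingSet:
    """Latent representations at every level of the model."""

    Z_c: np.ndarray  # n_c x d cell embeddings
    Z_g: np.ndarray  # n_g x d gene embeddings
    Z_g_star: np.ndarray  # n_c x d (mean) or n_c x g*d (concat) aggregated
    Z: np.ndarray  # n_c x (d + dim(Z_g_star)) combined


def gcn_forward(
    z_in: np.ndarray, propagation: np.ndarray | sp.spmatrix, params: GCNLayerParams
) -> np.ndarray:
    """One message-passing step: activation(P @ Z @ W)."""
    z_in = np.asarray(z_in, dtype=float)
    if propagation.shape[1] != z_in.shape[0]:
        raise ValueError(
            f"propagation {propagation.shape} incompatible with features {z_in.shape}"
        )
    if z_in.shape[1] != params.weight.shape[0]:
        raise ValueError(
            f"features {z_in.shape} incompatible with weights {params.weight.shape}"
        )
    return ACTIVATIONS[params.activation](propagation @ z_in @ params.weight)


def _run_stack(x, propagation, layers):
    z = x
    for layer in layers:
        z = gcn_forward(z, propagation, layer)
    return z


def encode(
    x_c: np.ndarray,
    a_c: np.ndarray | sp.spmatrix,
    x_g: np.ndarray,
    a_g: np.ndarray | sp.spmatrix,
    params: EncoderParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the two parallel encoders: Z_c = E_c(X_c, A_c), Z_g = E_g(X_g, A_g)."""
    p_c = normalize_adjacency(a_c)
    p_g = normalize_adjacency(a_g)
    return _run_stack(x_c, p_c, params.cell_layers), _run_stack(x_g, p_g, params.gene_layers)


def aggregate_gene_embeddings(
    z_g: np.ndarray, cell_of: np.ndarray, mode: str = "mean"
) -> np.ndarray:
    """Pool each cell's gene embeddings into one row.

    ``mean`` averages the rows belonging to each cell; ``concat`` concatenates
    them in vertex order (requires every cell to hold the same gene count).
    """
    z_g = np.asarray(z_g, dtype=float)
    cell_of = np.asarray(cell_of, dtype=int)
    if len(cell_of) != z_g.shape[0]:
        raise ValueError("cell_of length does not match the number of gene vertices")
    n_c = int(cell_of.max()) + 1 if len(cell_of) else 0
    counts = np.bincount(cell_of, minlength=n_c)
    if mode == "mean":
        out = np.zeros((n_c, z_g.shape[1]))
        np.add.at(out, cell_of, z_g)
        return out / counts[:, None]
    if mode == "concat":
        if len(set(counts.tolist())) != 1:
            raise ValueError("concat aggregation requires equal gene counts per cell")
        g = int(counts[0])
        order = np.lexsort((np.arange(len(cell_of)), cell_of))
        return z_g[order].reshape(n_c, g * z_g.shape[1])
    raise ValueError(f"unknown aggregation mode: {mode!r}")


def combine_embeddings(z_c: np.ndarray, z_g_star: np.ndarray) -> np.ndarray:
    """Columnwise concatenation Z = [Z_c | Z_g*]."""
    z_c, z_g_star = np.asarray(z_c, float), np.asarray(z_g_star, float)
    if z_c.shape[0] != z_g_star.shape[0]:
        raise ValueError(
            f"row mismatch: Z_c has {z_c.shape[0]} rows, Z_g* has {z_g_star.shape[0]}"
        )
    return np.hstack([z_c, z_g_star])


def decode_cell(z: np.ndarray, pairs: np.ndarray | None = None) -> np.ndarray:
    """Inner-product decoder: logistic(<z_i, z_j>).

    With ``pairs`` (an (m, 2) index array) only those entries are evaluated,
    which is the form needed at scale; otherwise the full symmetric matrix is
    returned.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("embeddings contain non-finite values")
    if pairs is None:
        return sigmoid(z @ z.T)
    pairs = np.asarray(pairs, dtype=int)
    return sigmoid(np.einsum("ij,ij->i", z[pairs[:, 0]], z[pairs[:, 1]]))


def decode_gene(
    z_g: np.ndarray,
    pairs: np.ndarray | None = None,
    block: int | None = None,
    g: int | None = None,
) -> np.ndarray:
    """Gene-level inner-product decoder over pairs or one diagonal block.

    ``block`` (with ``g`` genes per cell) evaluates the g x g reconstruction
    of that cell's GRN without materializing the full n_g x n_g matrix.
    """
    z_g = np.asarray(z_g, dtype=float)
    if block is not None:
        if g is None:
            raise ValueError("block evaluation requires g (genes per cell)")
        b = z_g[block * g : (block + 1) * g]
        return sigmoid(b @ b.T)
    return decode_cell(z_g, pairs=pairs)
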