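"""Reading and writing of external formats.

Spatial expression comes as a delimited cells-x-genes table (header = gene
names, first column = cell id) or a MatrixMarket triplet file with ``.rows`` /
``.cols`` name sidecars.  Coordinates are a delimited table with columns
``cell_id``, ``x``, ``y``; the order of cell ids in the coordinates file
defines the canonical cell order used everywhere downstream.

All emitted edge lists use 0-based vertex indices (documented in their file
headers).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "SpatialExpressionDataset",
    "LRDatabase",
    "AlignmentError",
    "ParseError",
    "load_spatial_expression",
    "load_lr_database",
    "load_grn_priors",
    "write_edge_list",
    "read_edge_list",
]


class AlignmentError(ValueError):
    """Cell identifiers do not match between expression and coordinates."""


class ParseError(ValueError):
    """A delimited input file is malformed."""


@dataclass
class SpatialExpressionDataset:
    """A cells-x-genes expression matrix with matching 2D cell coordinates.

    Parameters
    ----------
    cell_ids : array of str, length n_cells
    gene_names : array of str, length n_genes
    expression : (n_cells, n_genes) non-negative float array
    coordinates : (n_cells, 2) float array of spatial x, y
    cell_types : optional per-cell categorical labels
    """

    cell_ids: np.ndarray
    gene_names: np.ndarray
    expression: np.ndarray
    coordinates: np.ndarray
    cell_types: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.expression = np.asarray(self.expression, dtype=float)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        n_c = len(self.cell_ids)
        if self.expression.shape != (n_c, len(self.gene_names)):
            raise ValueError(
                f"expression shape {self.expression.shape} does not match "
                f"{n_c} cells x {len(self.gene_names)} genes"
            )
        if self.coordinates.shape != (n_c, 2):
            raise ValueError(
                f"coordinates shape {self.coordinates.shape}, expected ({n_c}, 2)"
            )
        if len(set(self.cell_ids)) != n_c:
            raise ValueError("cell_ids are not unique")
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValueError("gene_names are not unique")
        if not np.all(np.isfinite(self.expression)):
            raise ValueError("expression contains non-finite values")
        if np.any(self.expression < 0):
            raise ValueError("expression contains negative values")
        if self.cell_types is not None:
            self.cell_types = np.asarray(self.cell_types)
            if len(self.cell_types) != n_c:
                raise ValueError("cell_types length does not match cell count")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)


@dataclass
class LRDatabase:
    """A set of ordered (ligand, receptor) gene-symbol pairs."""

    pairs: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        seen: list[tuple[str, str]] = []
        for lig, rec in self.pairs:
            lig, rec = str(lig).strip(), str(rec).strip()
            if not lig or not rec:
                raise ValueError("empty gene symbol in ligand-receptor pair")
            if (lig, rec) not in seen:
                seen.append((lig, rec))
        self.pairs = tuple(seen)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def ligands(self) -> set[str]:
        return {lig for lig, _ in self.pairs}

    @property
    def receptors(self) -> set[str]:
        return {rec for _, rec in self.pairs}


def _read_delimited_expression(path: Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    return (
        df.index.astype(str).to_numpy(dtype=object),
        df.columns.astype(str).to_numpy(dtype=object),
        df.to_numpy(dtype=float),
    )


def _read_mtx_expression(path: Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mat = scipy.io.mmread(os.fspath(path))
    rows_path = path.with_suffix(path.suffix + ".rows")
    cols_path = path.with_suffix(path.suffix + ".cols")
    for side in (rows_path, cols_path):
        if not side.exists():
            raise FileNotFoundError(f"missing MatrixMarket name sidecar: {side}")
    cell_ids = np.array(rows_path.read_text().split(), dtype=object)
    gene_names = np.array(cols_path.read_text().split(), dtype=object)
    dense = np.asarray(sp.coo_matrix(mat).todense(), dtype=float)
    if dense.shape != (len(cell_ids), len(gene_names)):
        raise ValueError(
            f"matrix shape {dense.shape} does not match sidecars "
            f"({len(cell_ids)} cells, {len(gene_names)} genes)"
        )
    return cell_ids, gene_names, dense


def load_spatial_expression(
    expression_path: str | Path,
    coordinates_path: str | Path,
    normalize: bool = True,
) -> SpatialExpressionDataset:
    """Load expression + coordinates, aligning cells by id.

    The coordinates file defines the canonical cell order.  With
    ``normalize=True`` every count x is replaced by log(1 + x), the standard
    log transform for imaging-based spatial panels; pass ``False`` for inputs
    that are already normalized.
    """
    expression_path = Path(expression_path)
    coordinates_path = Path(coordinates_path)
    if expression_path.suffix == ".mtx":
        cell_ids, gene_names, expr = _read_mtx_expression(expression_path)
    else:
        cell_ids, gene_names, expr = _read_delimited_expression(expression_path)
    if np.any(expr < 0):
        raise ValueError("negative counts in expression matrix")

    coords_df = pd.read_csv(coordinates_path, sep=None, engine="python")
    required = {"cell_id", "x", "y"}
    if not required.issubset(coords_df.columns):
        raise ParseError(
            f"coordinates file must have columns cell_id, x, y; got {list(coords_df.columns)}"
        )
    coord_ids = coords_df["cell_id"].astype(str).to_numpy(dtype=object)

    expr_index = {cid: i for i, cid in enumerate(cell_ids)}
    missing_in_expr = [cid for cid in coord_ids if cid not in expr_index]
    coord_set = set(coord_ids)
    missing_in_coords = [cid for cid in cell_ids if cid not in coord_set]
    if missing_in_expr or missing_in_coords:
        parts = []
        if missing_in_expr:
            parts.append(f"ids missing from expression: {missing_in_expr[:10]}")
        if missing_in_coords:
            parts.append(f"ids missing from coordinates: {missing_in_coords[:10]}")
        raise AlignmentError("; ".join(parts))

    order = np.array([expr_index[cid] for cid in coord_ids])
    expr = expr[order]
    if normalize:
        expr = np.log1p(expr)
    return SpatialExpressionDataset(
        cell_ids=coord_ids,
        gene_names=gene_names,
        expression=expr,
        coordinates=coords_df[["x", "y"]].to_numpy(dtype=float),
    )


def load_lr_database(path: str | Path) -> LRDatabase:
    """Load a two-column (ligand, receptor) TSV; the header row is optional."""
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) == 1:  # tolerate comma/space separated rows
                fields = [f for f in line.replace(",", " ").split() if f]
            if len(fields) < 2:
                raise ParseError(f"line {lineno}: expected 2 fields, got {len(fields)}")
            lig, rec = fields[0], fields[1]
            if lineno == 1 and {lig.lower(), rec.lower()} == {"ligand", "receptor"}:
                continue
            pairs.append((lig, rec))
    return LRDatabase(pairs=tuple(pairs))


def _load_matrix_file(path: Path) -> np.ndarray:
    arr = pd.read_csv(path, sep=None, engine="python", header=None).to_numpy(dtype=float)
    return arr


def load_grn_priors(
    path: str | Path,
    n_cells: int | None = None,
    n_genes: int | None = None,
) -> list[np.ndarray]:
    """Load per-cell weighted g x g GRN matrices.

    ``path`` is either a directory of one headerless delimited matrix per
    cell (lexicographically sorted file names define cell order) or a single
    stacked file of n_cells * g rows that is split into consecutive g x g
    blocks.  Matrices are returned in canonical cell order; no symmetry is
    assumed at load time.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.is_file())
        mats = [_load_matrix_file(p) for p in files]
    else:
        stacked = _load_matrix_file(path)
        g = n_genes if n_genes is not None else stacked.shape[1]
        if stacked.shape[0] % g != 0:
            raise ValueError(
                f"stacked prior file has {stacked.shape[0]} rows, not a multiple of g={g}"
            )
        mats = [stacked[i : i + g] for i in range(0, stacked.shape[0], g)]
    for i, m in enumerate(mats):
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"GRN prior {i} has non-square shape {m.shape}")
        if n_genes is not None and m.shape[0] != n_genes:
            raise ValueError(
                f"GRN prior {i} is {m.shape[0]}x{m.shape[1]}, expected {n_genes}x{n_genes}"
            )
    if len({m.shape for m in mats}) > 1:
        raise ValueError("GRN priors have inconsistent shapes")
    if n_cells is not None and len(mats) != n_cells:
        raise ValueError(f"expected {n_cells} GRN priors, found {len(mats)}")
    return mats


def write_edge_list(
    edges: np.ndarray | sp.spmatrix | list[tuple[int, int, float]],
    path: str | Path,
    threshold: float | None = None,
) -> None:
    """Write edges as a TSV with columns source, target, score.

    Accepts a square (sparse or dense) matrix, in which case every nonzero
    entry becomes a row, or an iterable of (i, j, score) triples.  Rows are
    ordered by (source asc, target asc); with ``threshold`` only rows with
    score >= threshold are emitted.  Indices are 0-based.
    """
    if isinstance(edges, (np.ndarray, sp.spmatrix)) or sp.issparse(edges):
        if sp.issparse(edges):
            mat = sp.coo_matrix(edges)
            if mat.shape[0] != mat.shape[1]:
                raise ValueError(f"matrix is not square: {mat.shape}")
            triples = list(zip(mat.row.tolist(), mat.col.tolist(), mat.data.tolist()))
        else:
            mat = np.asarray(edges)
            if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
                raise ValueError(f"matrix is not square: {mat.shape}")
            ii, jj = np.nonzero(mat)
            triples = [(int(i), int(j), float(mat[i, j])) for i, j in zip(ii, jj)]
    else:
        triples = [(int(i), int(j), float(s)) for i, j, s in edges]
    if threshold is not None:
        triples = [t for t in triples if t[2] >= threshold]
    triples.sort(key=lambda t: (t[0], t[1]))
    with open(path, "w") as fh:
        fh.write("# source\ttarget\tscore (vertex indices are 0-based)\n")
        fh.write("source\ttarget\tscore\n")
        for i, j, s in triples:
            fh.write(f"{i}\t{j}\t{s:.10g}\n")


def read_edge_list(path: str | Path, n_vertices: int | None = None) -> np.ndarray:
    """Read a TSV written by :func:`write_edge_list` back into a dense matrix."""
    df = pd.read_csv(path, sep="\t", comment="#")
    n = n_vertices
    if n is None:
        n = int(max(df["source"].max(), df["target"].max())) + 1 if len(df) else 0
    out = np.zeros((n, n))
    for i, j, s in df.itertuples(index=False):
        out[int(i), int(j)] = s
    return out
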