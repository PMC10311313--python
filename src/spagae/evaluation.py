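"""Quantitative evaluation: link-prediction metrics, GRN scoring, and
spatial-refinement correlation analyses.

Link prediction on held-out cell edges is scored with average precision (the
recall-weighted mean of precisions, no interpolation) and AUROC (the
Mann-Whitney probability that a positive outranks a negative, ties counted
half).  Refined GRNs are scored against ground truth with the AUPRC ratio:
area under precision-recall divided by the positive density, so 1 is a
random-equivalent classifier and higher is better.

Spatial refinement is quantified by the Spearman rank correlation between a
reference cell-cell spatial distance matrix and a comparison distance matrix
computed from features, embeddings, or per-cell GRN matrices — either over
all unordered cell pairs or restricted to pairs inside the same block
(spatial community), mirroring how such heatmaps are read block by block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr
from sklearn.cluster import KMeans
from sklearn.metrics import average_precision_score, roc_auc_score

from .training import EdgeSplit

__all__ = [
    "EvalReport",
    "average_precision",
    "auroc",
    "auprc_ratio",
    "extract_refined_grns",
    "pairwise_distance_matrix",
    "spearman_spatial_refinement",
    "cluster_spatial_domains",
    "evaluate_embeddings",
]


@dataclass
class EvalReport:
    """Test-set link-prediction scores."""

    ap: float
    auroc: float
    n_pos: int
    n_neg: int
    split_descriptor: str = ""
    epoch: int | None = None

    def __str__(self) -> str:
        return (
            f"AP={self.ap:.4f} AUROC={self.auroc:.4f} "
            f"({self.n_pos} pos / {self.n_neg} neg; {self.split_descriptor})"
        )


def _check_two_classes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes")
    return labels


def average_precision(labels, scores) -> float:
    """Recall-weighted mean of precisions over descending score thresholds."""
    labels = _check_two_classes(labels)
    return float(average_precision_score(labels, np.asarray(scores, float)))


def auroc(labels, scores) -> float:
    """P(score_pos > score_neg) + 0.5 * P(tie)."""
    labels = _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores, float)))


def auprc_ratio(scores: np.ndarray, truth: np.ndarray) -> float:
    """AUPRC of off-diagonal scores against binary truth, over truth density.

    The diagonal is excluded.  A random or constant classifier scores ~1; a
    perfect one scores 1/density.
    """
    scores = np.asarray(scores, float)
    truth = np.asarray(truth, float)
    if scores.shape != truth.shape:
        raise ValueError(f"shape mismatch: {scores.shape} vs {truth.shape}")
    off = ~np.eye(truth.shape[0], dtype=bool)
    y = truth[off] > 0
    s = scores[off]
    if not y.any():
        raise ValueError("truth has no positive off-diagonal entry")
    density = y.mean()
    if y.all():
        return 1.0 / density  # degenerate: every pair is a positive
    return float(average_precision_score(y, s) / density)


def extract_refined_grns(
    z_g: np.ndarray, n_cells: int, g: int, threshold: float | None = None
) -> list[np.ndarray]:
    """Per-cell refined GRNs: decoded diagonal blocks of the gene adjacency."""
    from .gae import decode_gene

    out = []
    for c in range(n_cells):
        block = decode_gene(np.asarray(z_g, float), block=c, g=g)
        out.append((block >= threshold).astype(float) if threshold is not None else block)
    return out


def pairwise_distance_matrix(items, metric: str = "euclidean") -> np.ndarray:
    """Symmetric distance matrix between row vectors or between matrices.

    ``euclidean`` on a 2D array treats rows as points; on a list of matrices
    it flattens each matrix first.  ``frobenius`` requires matrix items and
    equals euclidean on the flattenings.
    """
    if isinstance(items, np.ndarray) and items.ndim == 2:
        if metric == "frobenius":
            raise ValueError("frobenius metric requires matrix-valued items")
        stack = np.asarray(items, float)
    else:
        mats = [np.asarray(m, float) for m in items]
        if len({m.shape for m in mats}) > 1:
            raise ValueError("items have heterogeneous shapes")
        if mats[0].ndim != 2 and metric == "frobenius":
            raise ValueError("frobenius metric requires matrix-valued items")
        stack = np.stack([m.ravel() for m in mats])
    if metric not in ("euclidean", "frobenius"):
        raise ValueError(f"unknown metric: {metric!r}")
    return squareform(pdist(stack, metric="euclidean"))


def _selected_pairs(n: int, restrict: str, labels) -> tuple[np.ndarray, np.ndarray]:
    iu, ju = np.triu_indices(n, k=1)
    if restrict == "entire":
        return iu, ju
    if restrict == "block_diagonal":
        if labels is None:
            raise ValueError("block_diagonal restriction requires block labels")
        labels = np.asarray(labels)
        same = labels[iu] == labels[ju]
        return iu[same], ju[same]
    raise ValueError(f"unknown restriction: {restrict!r}")


def spearman_spatial_refinement(
    reference: np.ndarray,
    comparison: np.ndarray,
    restrict: str = "entire",
    block_labels=None,
) -> tuple[float, float]:
    """Spearman correlation between two cell-pair distance matrices.

    Uses the strict upper triangle (each unordered pair once, diagonal
    excluded); ``restrict="block_diagonal"`` keeps only pairs whose two cells
    share a block label.  Returns (rho, p) with the large-sample p-value.
    """
    reference = np.asarray(reference, float)
    comparison = np.asarray(comparison, float)
    if reference.shape != comparison.shape:
        raise ValueError("distance matrices must share a shape")
    iu, ju = _selected_pairs(reference.shape[0], restrict, block_labels)
    if len(iu) < 3:
        raise ValueError("fewer than 3 selected pairs")
    rho, p = spearmanr(reference[iu, ju], comparison[iu, ju])
    return float(rho), float(p)


def cluster_spatial_domains(z: np.ndarray, k: int = 6, seed: int = 0) -> np.ndarray:
    """k-means domains on the rows of the (combined) embedding (default k=6)."""
    z = np.asarray(z, float)
    if k > z.shape[0]:
        raise ValueError(f"k={k} exceeds the number of cells ({z.shape[0]})")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    return km.fit_predict(z)


def evaluate_embeddings(
    z: np.ndarray, split: EdgeSplit, epoch: int | None = None
) -> EvalReport:
    """Score the held-out edge set with the inner-product decoder on Z."""
    from .gae import decode_cell

    if len(split.test_pos) == 0 or len(split.test_neg) == 0:
        raise ValueError("empty test set")
    pairs, labels = split.test_pairs_labels()
    scores = decode_cell(np.asarray(z, float), pairs=pairs)
    return EvalReport(
        ap=average_precision(labels, scores),
        auroc=auroc(labels, scores),
        n_pos=len(split.test_pos),
        n_neg=len(split.test_neg),
        split_descriptor=split.describe(),
        epoch=epoch,
    )
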