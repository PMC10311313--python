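"""The multi-level graph autoencoder as a fitted-model object.

``MultiLevelGAE`` is built from the two input graphs (or directly from a
:class:`~spagae.io.SpatialExpressionDataset` plus GRN priors and an LR
database via :meth:`MultiLevelGAE.from_dataset`); calling :meth:`fit` trains
the autoencoder by full-batch gradient descent (Adam) on

    L = lambda_c * BCE(cell edges) + lambda_g * MSE(GRN diagonal blocks)

and returns a :class:`GAEResults` carrying the learned weights, the
per-epoch loss table, the embeddings at every level, and accessors for the
two deliverables: cell-cell interaction scores and refined per-cell GRNs.

Gradients are derived in closed form (the model is a two-layer GCN stack per
level with an inner-product decoder, so backpropagation is a handful of
matrix products); a finite-difference test guards the derivation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .gae import (
    EmbeddingSet,
    aggregate_gene_embeddings,
    combine_embeddings,
    decode_cell,
    decode_gene,
    normalize_adjacency,
    sigmoid,
)
from .graphs import CellGraph, GeneGraph, assemble_gene_graph, binarize_grn_priors
from .features import compute_gene_features
from .training import (
    EdgeSplit,
    TrainConfig,
    _canon,
    _pair_set,
    _stack_blocks,
    build_block_mask,
    cell_loss,
    cell_loss_all_pairs,
    gene_loss,
    perturb_training_edges,
    split_edges,
    total_loss,
    training_adjacency,
)

__all__ = ["MultiLevelGAE", "GAEResults"]

WEIGHT_NAMES = ("W1c", "W2c", "W1g", "W2g")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class _Adam:
    """Adaptive-moment gradient descent over a dict of weight matrices."""

    def __init__(self, params, lr=0.01, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            m_hat = self.m[k] / (1 - self.b1**self.t)
            v_hat = self.v[k] / (1 - self.b2**self.t)
            params[k] = params[k] - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class MultiLevelGAE:
    """Two-level graph autoencoder over a cell proximity graph and a gene graph.

    Parameters
    ----------
    cell_graph : CellGraph
        Spatial kNN adjacency and expression features.
    gene_graph : GeneGraph
        Block-diagonal GRNs with LR cross edges; ``features`` must be filled.
    config : TrainConfig, optional
        Default hyperparameters for :meth:`fit`.
    """

    def __init__(self, cell_graph: CellGraph, gene_graph: GeneGraph,
                 config: TrainConfig | None = None, standardize_features: bool = True):
        if gene_graph.features is None:
            raise ValueError("gene_graph.features not computed; run compute_gene_features")
        if gene_graph.n_cells != cell_graph.n_cells:
            raise ValueError("cell and gene graphs disagree on the number of cells")
        self.cell_graph = cell_graph
        self.gene_graph = gene_graph
        self.config = config or TrainConfig()
        # conditioning: per-gene standardization of the expression features keeps
        # the initial decoder logits near zero (unstandardized log-counts start
        # the BCE deep in logistic saturation); the graph objects keep the
        # original features for feature-vs-embedding comparisons downstream
        if standardize_features:
            x = np.asarray(cell_graph.features, float)
            self._x_cell = (x - x.mean(axis=0)) / (x.std(axis=0) + 1e-12)
        else:
            self._x_cell = np.asarray(cell_graph.features, float)

    @classmethod
    def from_dataset(
        cls,
        dataset,
        grn_priors: list[np.ndarray],
        lr_db,
        k: int = 6,
        config: TrainConfig | None = None,
        binarize_rule: str = "absolute",
        binarize_threshold: float | None = None,
        binarize_q: float | None = None,
        feature_dim: int = 32,
        feature_seed: int = 0,
        feature_scope: str = "blocks",
        **feature_kwargs,
    ) -> "MultiLevelGAE":
        """Build both graphs and gene features from raw inputs in one step."""
        from .graphs import build_cell_graph

        cell_graph = build_cell_graph(dataset, k=k)
        priors = binarize_grn_priors(
            grn_priors, rule=binarize_rule, threshold=binarize_threshold, q=binarize_q
        )
        gene_graph = assemble_gene_graph(cell_graph, priors, dataset.gene_names, lr_db)
        compute_gene_features(
            gene_graph, dim=feature_dim, seed=feature_seed, scope=feature_scope,
            **feature_kwargs,
        )
        return cls(cell_graph, gene_graph, config=config)

    # ----------------------------------------------------------------- params
    def init_params(self, seed: int) -> dict[str, np.ndarray]:
        """Glorot-uniform weight initialization for both encoder stacks."""
        cfg = self.config
        rng = np.random.default_rng(seed)
        f_c = self.cell_graph.features.shape[1]
        f_g = self.gene_graph.features.shape[1]
        return {
            "W1c": _glorot(rng, f_c, cfg.hidden_dim),
            "W2c": _glorot(rng, cfg.hidden_dim, cfg.latent_dim),
            "W1g": _glorot(rng, f_g, cfg.hidden_dim),
            "W2g": _glorot(rng, cfg.hidden_dim, cfg.latent_dim),
        }

    # ---------------------------------------------------------------- forward
    def _forward(self, params, a1c, p_c, a1g, p_g, cfg: TrainConfig):
        pre_c = a1c @ params["W1c"]
        h_c = np.maximum(pre_c, 0.0) if cfg.activation == "relu" else pre_c
        m_c = p_c @ h_c
        z_c = m_c @ params["W2c"]

        pre_g = a1g @ params["W1g"]
        h_g = np.maximum(pre_g, 0.0) if cfg.activation == "relu" else pre_g
        m_g = p_g @ h_g
        z_g = m_g @ params["W2g"]

        cell_of = self.gene_graph.cell_of
        s = aggregate_gene_embeddings(z_g, cell_of, mode=cfg.aggregation)
        if cfg.zero_gene_in_combined:
            s = np.zeros_like(s)
        z = combine_embeddings(z_c, s)
        cache = dict(pre_c=pre_c, m_c=m_c, pre_g=pre_g, m_g=m_g,
                     z_c=z_c, z_g=z_g, s=s, z=z)
        return cache

    def _embeddings(self, params, split: EdgeSplit | None = None,
                    train_pos: np.ndarray | None = None,
                    cfg: TrainConfig | None = None) -> EmbeddingSet:
        """Forward pass with the propagation graphs implied by the split."""
        cfg = cfg or self.config
        p_c, p_g = self._propagation(split, train_pos)
        a1c = p_c @ self._x_cell
        a1g = p_g @ self.gene_graph.features
        c = self._forward(params, a1c, p_c, a1g, p_g, cfg)
        return EmbeddingSet(Z_c=c["z_c"], Z_g=c["z_g"], Z_g_star=c["s"], Z=c["z"])

    def _propagation(self, split, train_pos=None):
        if split is None:
            a_train = self.cell_graph.adjacency
        else:
            pos = train_pos if train_pos is not None else split.train_pos
            a_train = training_adjacency(split.n_cells, pos)
        p_c = normalize_adjacency(a_train)
        p_g = normalize_adjacency(self.gene_graph.with_cell_adjacency(a_train))
        return p_c, p_g

    # -------------------------------------------------------- loss + gradient
    def _loss_and_grads(self, params, a1c, p_c, a1g, p_g, pairs, labels,
                        target_blocks, a_train, cfg: TrainConfig):
        n_c = self.cell_graph.n_cells
        g = self.gene_graph.g
        d = cfg.latent_dim
        c = self._forward(params, a1c, p_c, a1g, p_g, cfg)
        z, z_g = c["z"], c["z_g"]

        # cell-level BCE
        if cfg.loss_mode == "sampled":
            t = np.einsum("ij,ij->i", z[pairs[:, 0]], z[pairs[:, 1]])
            p = sigmoid(t)
            l_c = cell_loss(p, labels)
            g_t = (p - labels) / len(labels)
            g_z = np.zeros_like(z)
            np.add.at(g_z, pairs[:, 0], g_t[:, None] * z[pairs[:, 1]])
            np.add.at(g_z, pairs[:, 1], g_t[:, None] * z[pairs[:, 0]])
        else:
            a_full = np.asarray(a_train.todense())
            p_mat = sigmoid(z @ z.T)
            l_c = cell_loss_all_pairs(a_full, p_mat)
            e = (p_mat - a_full) / (n_c * n_c)
            g_z = (e + e.T) @ z
        g_z = cfg.lambda_c * g_z

        # gene-level masked MSE, blockwise
        zb = z_g.reshape(n_c, g, -1)
        t_blocks = np.einsum("cgd,chd->cgh", zb, zb)
        p_blocks = sigmoid(t_blocks)
        diff = p_blocks - target_blocks
        l_g = float(np.sum(diff**2) / (n_c * g * g))
        gt = 2.0 * diff * p_blocks * (1.0 - p_blocks) / (n_c * g * g)
        g_zb = np.einsum("cgh,chd->cgd", gt + gt.transpose(0, 2, 1), zb)
        g_zg = cfg.lambda_g * g_zb.reshape(z_g.shape)

        # split combined-embedding gradient into the two branches
        g_zc = g_z[:, :d]
        g_s = g_z[:, d:]
        if not cfg.zero_gene_in_combined:
            if cfg.aggregation == "mean":
                g_zg = g_zg + np.repeat(g_s / g, g, axis=0)
            else:  # concat
                g_zg = g_zg + g_s.reshape(z_g.shape)

        grads = {}
        # cell branch
        grads["W2c"] = c["m_c"].T @ g_zc
        d_m = g_zc @ params["W2c"].T
        d_h = p_c.T @ d_m
        d_pre = d_h * (c["pre_c"] > 0) if cfg.activation == "relu" else d_h
        grads["W1c"] = a1c.T @ d_pre
        # gene branch
        grads["W2g"] = c["m_g"].T @ g_zg
        d_mg = g_zg @ params["W2g"].T
        d_hg = p_g.T @ d_mg
        d_preg = d_hg * (c["pre_g"] > 0) if cfg.activation == "relu" else d_hg
        grads["W1g"] = a1g.T @ d_preg

        return l_c, l_g, total_loss(l_c, l_g, cfg), grads, c

    # -------------------------------------------------------------------- fit
    def fit(
        self,
        split: EdgeSplit | None = None,
        test_fraction: float = 0.3,
        seed: int | None = None,
        fp_rate: float = 0.0,
        fn_rate: float = 0.0,
        **config_overrides,
    ) -> "GAEResults":
        """Train the autoencoder and return a results object.

        The training graph is the proximity graph with test edges removed
        (and, if ``fp_rate``/``fn_rate`` are set, perturbed with fake /
        deleted edges per the robustness protocol).  Deterministic for a
        fixed seed.
        """
        cfg = self.config.replace(**config_overrides) if config_overrides else self.config
        if seed is not None:
            cfg = cfg.replace(seed=seed)
        if split is None:
            split = split_edges(self.cell_graph.adjacency, test_fraction, cfg.seed)

        train_pos = split.train_pos
        if fp_rate > 0 or fn_rate > 0:
            candidates = self._non_edge_candidates(split, fp_rate, cfg.seed)
            train_pos = perturb_training_edges(
                split.train_pos, fp_rate, fn_rate, candidates, cfg.seed
            )

        a_train = training_adjacency(split.n_cells, train_pos)
        # leakage guard: no test positive may sit in the propagation graph
        leaked = _pair_set(train_pos) & _pair_set(split.test_pos)
        if leaked:
            raise RuntimeError(f"test edges leaked into training graph: {sorted(leaked)[:5]}")

        p_c = normalize_adjacency(a_train)
        p_g = normalize_adjacency(self.gene_graph.with_cell_adjacency(a_train))
        a1c = p_c @ self._x_cell
        a1g = p_g @ self.gene_graph.features
        n_c, g = self.cell_graph.n_cells, self.gene_graph.g
        # gene-level reconstruction target: GRN blocks with self-loops (A + I),
        # the usual GAE convention; a zero diagonal makes Z_g = 0 an attractor
        target_blocks = _stack_blocks(self.gene_graph.block_diagonal_only(), n_c, g)
        target_blocks = target_blocks + np.eye(g)[None, :, :]

        pairs = np.vstack([train_pos, split.train_neg]).astype(int)
        labels = np.concatenate([np.ones(len(train_pos)), np.zeros(len(split.train_neg))])

        params = self.init_params(cfg.seed)
        opt = _Adam(params, lr=cfg.learning_rate)
        test_pairs, test_labels = split.test_pairs_labels()

        rows = []
        for epoch in range(1, cfg.epochs + 1):
            l_c, l_g, l_tot, grads, cache = self._loss_and_grads(
                params, a1c, p_c, a1g, p_g, pairs, labels, target_blocks, a_train, cfg
            )
            if not np.isfinite(l_tot):
                raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
            row = {"epoch": epoch, "loss_cell": l_c, "loss_gene": l_g, "loss_total": l_tot,
                   "test_ap": np.nan, "test_auroc": np.nan}
            if epoch % cfg.eval_every == 0 or epoch == cfg.epochs:
                from .evaluation import average_precision, auroc

                scores = decode_cell(cache["z"], pairs=test_pairs)
                row["test_ap"] = average_precision(test_labels, scores)
                row["test_auroc"] = auroc(test_labels, scores)
            rows.append(row)
            opt.step(params, grads)

        embeddings = self._embeddings(params, split, train_pos, cfg)
        report = pd.DataFrame(rows, columns=["epoch", "loss_cell", "loss_gene",
                                             "loss_total", "test_ap", "test_auroc"])
        return GAEResults(model=self, params=params, config=cfg, split=split,
                          loss_report=report, embeddings=embeddings,
                          train_pos_used=train_pos)

    def _non_edge_candidates(self, split: EdgeSplit, fp_rate: float, seed: int) -> np.ndarray:
        """Uniform non-edge pairs disjoint from all split sets, for fp noise."""
        n = split.n_cells
        needed = int(np.floor(fp_rate * len(split.train_pos)))
        forbidden = (
            _pair_set(split.train_pos) | _pair_set(split.test_pos)
            | _pair_set(split.train_neg) | _pair_set(split.test_neg)
        )
        rng = np.random.default_rng(seed + 1_000_003)
        out: list[tuple[int, int]] = []
        chosen: set[tuple[int, int]] = set()
        attempts = 0
        while len(out) < needed:
            attempts += 1
            if attempts > 200:
                raise ValueError("insufficient non-edge candidates for fp perturbation")
            ii = rng.integers(0, n, size=max(4 * needed, 64))
            jj = rng.integers(0, n, size=len(ii))
            for i, j in zip(ii, jj):
                if i == j:
                    continue
                pair = (int(min(i, j)), int(max(i, j)))
                if pair in forbidden or pair in chosen:
                    continue
                chosen.add(pair)
                out.append(pair)
                if len(out) == needed:
                    break
        return np.array(out, dtype=np.int64).reshape(-1, 2)

    def results_from_checkpoint(self, path: str | Path) -> "GAEResults":
        """Rebuild a results object (weights, split, embeddings) from disk."""
        return GAEResults.load(path, self)


@dataclass
class GAEResults:
    """Fitted multi-level GAE: weights, loss history, embeddings, accessors."""

    model: MultiLevelGAE
    params: dict[str, np.ndarray]
    config: TrainConfig
    split: EdgeSplit
    loss_report: pd.DataFrame
    embeddings: EmbeddingSet
    train_pos_used: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))

    # ------------------------------------------------------------- deliverables
    def predict_cci(self, pairs: np.ndarray | None = None) -> np.ndarray:
        """Cell-cell interaction scores from the combined embedding."""
        return decode_cell(self.embeddings.Z, pairs=pairs)

    def refined_grns(self, threshold: float | None = None) -> list[np.ndarray]:
        """Per-cell refined GRNs: the decoded gene-level diagonal blocks."""
        g = self.model.gene_graph.g
        out = []
        for c in range(self.model.cell_graph.n_cells):
            block = decode_gene(self.embeddings.Z_g, block=c, g=g)
            out.append((block >= threshold).astype(float) if threshold is not None else block)
        return out

    def evaluate(self, epoch: int | None = None):
        """Test-set AP / AUROC report on the held-out edges."""
        from .evaluation import evaluate_embeddings

        return evaluate_embeddings(self.embeddings.Z, self.split, epoch=epoch)

    # ------------------------------------------------------------------ summary
    def summary(self) -> str:
        rep = self.evaluate()
        last = self.loss_report.iloc[-1] if len(self.loss_report) else None
        lines = [
            "Multi-level graph autoencoder results",
            "=" * 53,
            f"cells: {self.model.cell_graph.n_cells}   genes/cell: {self.model.gene_graph.g}"
            f"   gene vertices: {self.model.gene_graph.n_vertices}",
            f"latent dim: {self.config.latent_dim}   aggregation: {self.config.aggregation}"
            f"   lambda_c: {self.config.lambda_c}   lambda_g: {self.config.lambda_g}",
            f"epochs: {self.config.epochs}   lr: {self.config.learning_rate}"
            f"   seed: {self.config.seed}",
            f"edge split: {self.split.describe()}",
        ]
        if last is not None:
            lines.append(
                f"final losses: L_c={last.loss_cell:.4f}  L_g={last.loss_gene:.4f}"
                f"  L={last.loss_total:.4f}"
            )
        lines.append(f"test AP: {rep.ap:.4f}   test AUROC: {rep.auroc:.4f}")
        lines.append("=" * 53)
        return "\n".join(lines)

    # ----------------------------------------------------------------- storage
    def save(self, path: str | Path) -> None:
        """One archive: weight matrices + config JSON + split arrays."""
        cfg_json = json.dumps(self.config.__dict__)
        np.savez(
            path,
            __config=np.array(cfg_json),
            __train_pos_used=self.train_pos_used,
            split_train_pos=self.split.train_pos,
            split_test_pos=self.split.test_pos,
            split_train_neg=self.split.train_neg,
            split_test_neg=self.split.test_neg,
            split_meta=np.array(
                [self.split.n_cells, self.split.test_fraction, self.split.seed]
            ),
            **self.params,
        )

    @classmethod
    def load(cls, path: str | Path, model: MultiLevelGAE) -> "GAEResults":
        with np.load(Path(path).with_suffix(".npz") if not str(path).endswith(".npz") else path,
                     allow_pickle=False) as ck:
            cfg = TrainConfig(**json.loads(str(ck["__config"])))
            params = {k: ck[k] for k in WEIGHT_NAMES}
            meta = ck["split_meta"]
            split = EdgeSplit(
                train_pos=ck["split_train_pos"], test_pos=ck["split_test_pos"],
                train_neg=ck["split_train_neg"], test_neg=ck["split_test_neg"],
                n_cells=int(meta[0]), test_fraction=float(meta[1]), seed=int(meta[2]),
            )
            train_pos_used = ck["__train_pos_used"]
        embeddings = model._embeddings(params, split, train_pos_used, cfg)
        return cls(model=model, params=params, config=cfg, split=split,
                   loss_report=pd.DataFrame(), embeddings=embeddings,
                   train_pos_used=train_pos_used)

    def export_embeddings(self, path: str | Path) -> None:
        """Combined embedding Z as a TSV (one row per cell)."""
        pd.DataFrame(self.embeddings.Z).to_csv(path, sep="\t", index=False,
                                               header=False, float_format="%.8g")
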