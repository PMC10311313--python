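import numpy as np
import pytest
import scipy.sparse as sp

from spagae.graphs import (
    DEFAULT_K,
    assemble_gene_graph,
    binarize_grn_priors,
    build_cell_graph,
    identify_lr_vertices,
)
from spagae.io import LRDatabase

from conftest import make_dataset


def brute_force_knn(coords, k):
    """Independent kNN-union oracle: sort by (distance, index) per vertex."""
    n = len(coords)
    adj = np.zeros((n, n))
    for i in range(n):
        d = [(np.linalg.norm(coords[i] - coords[j]), j) for j in range(n) if j != i]
        for _, j in sorted(d)[:k]:
            adj[i, j] = adj[j, i] = 1
    return adj


class TestCellGraph:
    def test_two_cells_single_edge(self):
        ds = make_dataset([[0, 0], [1, 0]])
        cg = build_cell_graph(ds, k=1)
        np.testing.assert_array_equal(cg.adjacency.todense(), [[0, 1], [1, 0]])

    def test_union_symmetrization_on_line(self):
        ds = make_dataset([[0, 0], [1, 0], [2, 0], [10, 0]])
        cg = build_cell_graph(ds, k=1)
        # cell 3's nearest is 2, so union symmetrization creates edge 2-3
        expected = {(0, 1), (1, 2), (2, 3)}
        assert set(map(tuple, cg.edge_array())) == expected

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        coords = rng.uniform(size=(50, 2))
        ds = make_dataset(coords, expression=rng.uniform(size=(50, 3)))
        for k in (1, 3, 6):
            cg = build_cell_graph(ds, k=k)
            np.testing.assert_array_equal(
                np.asarray(cg.adjacency.todense()), brute_force_knn(coords, k)
            )

    def test_default_k_satisfies_local_interaction_assumption(self):
        # each cell is assumed to interact locally with at least 3 neighbours
        assert DEFAULT_K >= 3
        rng = np.random.default_rng(0)
        ds = make_dataset(rng.uniform(size=(30, 2)))
        cg = build_cell_graph(ds)
        assert np.all(np.asarray(cg.adjacency.sum(axis=1)).ravel() >= cg.k)

    def test_k_too_large_rejected(self):
        ds = make_dataset([[0, 0], [1, 0]])
        with pytest.raises(ValueError, match="k="):
            build_cell_graph(ds, k=2)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(size=(40, 2))
        theta = 0.83
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = coords @ rot.T + np.array([5.0, -2.0])
        a = build_cell_graph(make_dataset(coords), k=4).adjacency
        b = build_cell_graph(make_dataset(moved), k=4).adjacency
        assert (a != b).nnz == 0

    def test_cell_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        coords = rng.uniform(size=(20, 2))
        perm = rng.permutation(20)
        a = np.asarray(build_cell_graph(make_dataset(coords), k=3).adjacency.todense())
        b = np.asarray(build_cell_graph(make_dataset(coords[perm]), k=3).adjacency.todense())
        np.testing.assert_array_equal(b, a[np.ix_(perm, perm)])


class TestBinarize:
    def test_absolute_threshold(self):
        [prior] = binarize_grn_priors([np.array([[0, 0.9], [0.9, 0]])], threshold=0.5)
        np.testing.assert_array_equal(prior.binary, [[0, 1], [1, 0]])

    def test_all_zero_matrix(self):
        for rule, kw in (("absolute", {}), ("top_q", {"q": 0.25})):
            [prior] = binarize_grn_priors([np.zeros((3, 3))], rule=rule, **kw)
            assert prior.binary.sum() == 0

    def test_top_q_matches_sort_and_cut_oracle(self):
        rng = np.random.default_rng(11)
        w = rng.normal(size=(4, 4))
        np.fill_diagonal(w, 0.0)
        [prior] = binarize_grn_priors([w], rule="top_q", q=0.25)
        sym = np.maximum(np.abs(w), np.abs(w.T))
        iu = np.triu_indices(4, k=1)
        keep = int(np.floor(0.25 * len(iu[0])))
        top = np.argsort(-sym[iu], kind="stable")[:keep]
        expected = np.zeros((4, 4))
        expected[iu[0][top], iu[1][top]] = 1
        expected = np.maximum(expected, expected.T)
        np.testing.assert_array_equal(prior.binary, expected)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            binarize_grn_priors([np.array([[0, np.nan], [1, 0]])])

    def test_default_percentile_rule(self):
        rng = np.random.default_rng(5)
        w = rng.normal(size=(10, 10))
        [prior] = binarize_grn_priors([w])
        sym = np.maximum(np.abs(w), np.abs(w.T))
        np.fill_diagonal(sym, 0)
        iu = np.triu_indices(10, k=1)
        assert prior.threshold_used == pytest.approx(np.quantile(sym[iu], 0.9))
        np.testing.assert_array_equal(prior.binary, (sym >= prior.threshold_used))


class TestLRVertices:
    def test_direct_lookup(self):
        lig, rec = identify_lr_vertices(["A", "B", "C"], LRDatabase((("A", "C"),)))
        assert (lig, rec) == ({0}, {2})

    def test_empty_database(self):
        assert identify_lr_vertices(["A"], LRDatabase()) == (set(), set())

    def test_gene_in_both_roles(self):
        lig, rec = identify_lr_vertices(
            ["A", "B"], LRDatabase((("A", "B"), ("B", "A")))
        )
        assert lig == {0, 1} and rec == {0, 1}


def _two_cell_setup(adjacent=True, lr_pairs=(("A", "C"),)):
    coords = [[0, 0], [1, 0]] if adjacent else [[0, 0], [1, 0]]
    ds = make_dataset(coords, expression=np.ones((2, 3)), gene_names=["A", "B", "C"])
    cg = build_cell_graph(ds, k=1)
    if not adjacent:
        cg.adjacency = sp.csr_matrix((2, 2))
    grn = np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0]], float)  # A-B edge
    return cg, [grn, grn], ["A", "B", "C"], LRDatabase(tuple(lr_pairs))


class TestGeneGraph:
    def test_worked_example(self):
        cg, grns, names, db = _two_cell_setup()
        gg = assemble_gene_graph(cg, grns, names, db)
        assert gg.adjacency.nnz == 8  # 4 GRN entries + 4 LR entries, symmetric
        dense = np.asarray(gg.adjacency.todense())
        # undirected edges: A0-B0, A1-B1, A0-C1, A1-C0  (A=0,B=1,C=2; cell 1 offset 3)
        for u, v in [(0, 1), (3, 4), (0, 5), (3, 2)]:
            assert dense[u, v] == 1 and dense[v, u] == 1

    def test_no_proximity_means_block_diagonal(self):
        cg, grns, names, db = _two_cell_setup(adjacent=False)
        gg = assemble_gene_graph(cg, grns, names, db)
        assert gg.adjacency.nnz == 4
        assert (gg.adjacency != gg.block_diagonal_only()).nnz == 0

    def test_absent_lr_genes_means_block_diagonal(self):
        cg, grns, names, _ = _two_cell_setup()
        gg = assemble_gene_graph(cg, grns, names, LRDatabase((("X", "Y"),)))
        assert gg.adjacency.nnz == 4

    def test_blocks_equal_input_grns(self, easy_model):
        gg = easy_model.gene_graph
        rng = np.random.default_rng(0)
        for c in rng.integers(0, gg.n_cells, size=5):
            block = gg.block(int(c))
            assert block.shape == (gg.g, gg.g)
            np.testing.assert_array_equal(block, block.T)
            assert np.all(np.diag(block) == 0)

    def test_off_block_count_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(9)
        coords = rng.uniform(size=(5, 2))
        names = ["A", "B", "C", "D"]
        ds = make_dataset(coords, expression=rng.uniform(size=(5, 4)), gene_names=names)
        cg = build_cell_graph(ds, k=2)
        grn = np.zeros((4, 4))
        pairs = (("A", "B"), ("C", "D"), ("B", "C"))
        gg = assemble_gene_graph(cg, [grn] * 5, names, LRDatabase(pairs))
        # oracle: loop over cell edges x ordered LR pairs, both directions
        name_idx = {n: i for i, n in enumerate(names)}
        edges = set()
        adj = np.asarray(cg.adjacency.todense())
        for i in range(5):
            for j in range(5):
                if i == j or not adj[i, j]:
                    continue
                for l, r in pairs:
                    u, v = i * 4 + name_idx[l], j * 4 + name_idx[r]
                    edges.add((min(u, v), max(u, v)))
        assert gg.adjacency.nnz == 2 * len(edges)

    def test_grn_count_mismatch_rejected(self):
        cg, grns, names, db = _two_cell_setup()
        with pytest.raises(ValueError, match="GRNs"):
            assemble_gene_graph(cg, grns[:1], names, db)

    def test_vertex_bookkeeping(self):
        cg, grns, names, db = _two_cell_setup()
        gg = assemble_gene_graph(cg, grns, names, db)
        assert gg.n_vertices == 6
        np.testing.assert_array_equal(gg.cell_of, [0, 0, 0, 1, 1, 1])
        assert gg.gene_of(4) == "B"
        lig, rec = gg.lr_vertices(1)
        assert list(lig) == [3] and list(rec) == [5]
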