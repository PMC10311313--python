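import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spagae.evaluation import (
    _selected_pairs,
    auprc_ratio,
    auroc,
    average_precision,
    cluster_spatial_domains,
    evaluate_embeddings,
    pairwise_distance_matrix,
    spearman_spatial_refinement,
)
from spagae.training import EdgeSplit


def ap_oracle(labels, scores):
    """Threshold-enumeration AP: sum of (R_k - R_{k-1}) * P_k, no interpolation."""
    labels = np.asarray(labels, float)
    order = np.argsort(-np.asarray(scores, float), kind="stable")
    labels = labels[order]
    scores = np.asarray(scores, float)[order]
    n_pos = labels.sum()
    ap, prev_recall = 0.0, 0.0
    tp = fp = 0
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and scores[j] == scores[i]:
            tp += labels[j]
            fp += 1 - labels[j]
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return ap


def auroc_oracle(labels, scores):
    """All-pairs Mann-Whitney: P(pos > neg) + 0.5 P(tie)."""
    labels = np.asarray(labels)
    pos = np.asarray(scores, float)[labels == 1]
    neg = np.asarray(scores, float)[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAveragePrecision:
    def test_perfect_ranking(self):
        assert average_precision([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == pytest.approx(1.0)

    def test_worked_case(self):
        got = average_precision([1, 0, 1], [0.9, 0.8, 0.7])
        assert got == pytest.approx(0.5 * 1 + 0.5 * (2 / 3), abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 31))
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.round(rng.uniform(size=n), 2)  # provoke ties
        assert average_precision(labels, scores) == pytest.approx(
            ap_oracle(labels, scores), abs=1e-12
        )

    def test_random_scores_near_half(self):
        # balanced labels, random scores: AP is prevalence (0.5) in
        # expectation up to a small finite-sample bias
        rng = np.random.default_rng(0)
        aps = []
        for _ in range(1000):
            labels = np.array([1] * 50 + [0] * 50)
            aps.append(average_precision(labels, rng.uniform(size=100)))
        assert np.mean(aps) == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            average_precision([1, 1], [0.5, 0.4])


class TestAUROC:
    def test_perfect_and_inverted(self):
        assert auroc([1, 1, 0], [0.9, 0.8, 0.1]) == pytest.approx(1.0)
        assert auroc([1, 0], [0.3, 0.7]) == pytest.approx(0.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_mann_whitney_oracle(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, size=20)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.round(rng.uniform(size=20), 1)
        assert auroc(labels, scores) == pytest.approx(
            auroc_oracle(labels, scores), abs=1e-12
        )

    def test_all_ties_give_half(self):
        assert auroc([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5]) == pytest.approx(0.5)


class TestAUPRCRatio:
    def _truth(self):
        t = np.zeros((4, 4))
        t[0, 1] = t[1, 0] = t[2, 3] = t[3, 2] = 1  # density 4/12 = 1/3
        return t

    def test_perfect_classifier(self):
        truth = np.zeros((4, 4))
        truth[0, 1] = truth[1, 0] = 1
        truth[0, 2] = truth[2, 0] = 1  # density 4/12 = 1/3... use explicit
        scores = truth * 0.9 + 0.05
        density = truth[~np.eye(4, dtype=bool)].mean()
        assert auprc_ratio(scores, truth) == pytest.approx(1.0 / density)

    def test_quarter_density_perfect_is_four(self):
        truth = np.zeros((5, 5))
        # 5 of 20 off-diagonal entries positive -> density 0.25
        for u, v in [(0, 1), (1, 0), (2, 3), (3, 2), (0, 4)]:
            truth[u, v] = 1
        scores = truth.copy()
        scores = scores * 0.8 + 0.1
        assert auprc_ratio(scores, truth) == pytest.approx(4.0)

    def test_constant_scores_are_random_equivalent(self):
        truth = self._truth()
        assert auprc_ratio(np.full((4, 4), 0.3), truth) == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        truth = self._truth()
        scores = rng.uniform(size=(4, 4))
        a = auprc_ratio(scores, truth)
        b = auprc_ratio(np.exp(3 * scores), truth)
        assert a == pytest.approx(b, abs=1e-12)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            auprc_ratio(np.ones((3, 3)), np.eye(3))


class TestDistances:
    def test_three_four_five(self):
        d = pairwise_distance_matrix(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert d[0, 1] == pytest.approx(5.0)
        assert d[0, 0] == 0.0

    def test_identical_items_zero(self):
        mats = [np.ones((2, 2)), np.ones((2, 2))]
        assert pairwise_distance_matrix(mats, metric="frobenius")[0, 1] == 0.0

    def test_frobenius_equals_flattened_euclidean(self):
        rng = np.random.default_rng(2)
        mats = [rng.normal(size=(3, 3)) for _ in range(4)]
        a = pairwise_distance_matrix(mats, metric="frobenius")
        b = pairwise_distance_matrix(np.stack([m.ravel() for m in mats]))
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_shape_heterogeneity_rejected(self):
        with pytest.raises(ValueError, match="heterogeneous"):
            pairwise_distance_matrix([np.zeros((2, 2)), np.zeros((3, 3))])

    def test_frobenius_needs_matrices(self):
        with pytest.raises(ValueError, match="matrix"):
            pairwise_distance_matrix(np.zeros((3, 2)), metric="frobenius")


class TestSpearman:
    def _dist(self, rng, n=6):
        x = rng.normal(size=(n, 2))
        return pairwise_distance_matrix(x)

    def test_identical_rankings(self):
        d = self._dist(np.random.default_rng(3))
        rho, p = spearman_spatial_refinement(d, d)
        assert rho == pytest.approx(1.0)
        assert p < 0.05

    def test_reversed_rankings(self):
        d = self._dist(np.random.default_rng(4))
        rho, _ = spearman_spatial_refinement(d, d.max() - d)
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(5)
        d1, d2 = self._dist(rng, 4), self._dist(rng, 4)
        rho, _ = spearman_spatial_refinement(d1, d2)
        iu = np.triu_indices(4, k=1)
        a, b = d1[iu], d2[iu]
        ra = np.argsort(np.argsort(a)).astype(float)
        rb = np.argsort(np.argsort(b)).astype(float)
        oracle = np.corrcoef(ra, rb)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_block_restriction_pair_count(self):
        labels = np.array([0, 0, 0, 1, 1, 2])
        iu, ju = _selected_pairs(6, "block_diagonal", labels)
        # sum of (n_b choose 2) = 3 + 1 + 0
        assert len(iu) == 4
        assert np.all(labels[iu] == labels[ju])

    def test_too_few_pairs_rejected(self):
        d = self._dist(np.random.default_rng(6), 4)
        with pytest.raises(ValueError, match="fewer than 3"):
            spearman_spatial_refinement(d, d, "block_diagonal", np.array([0, 1, 2, 3]))


class TestDomains:
    def test_single_cluster_degenerate(self):
        z = np.random.default_rng(7).normal(size=(10, 3))
        assert set(cluster_spatial_domains(z, k=1, seed=0)) == {0}

    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=(20, 2)) * 0.1
        b = rng.normal(size=(20, 2)) * 0.1 + 50.0
        labels = cluster_spatial_domains(np.vstack([a, b]), k=2, seed=0)
        assert len(set(labels[:20])) == 1
        assert len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]

    def test_k_exceeding_cells_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            cluster_spatial_domains(np.zeros((3, 2)), k=5)


class TestEvaluateEmbeddings:
    def _split(self):
        return EdgeSplit(
            train_pos=np.array([[0, 1]]), test_pos=np.array([[1, 2], [2, 3]]),
            train_neg=np.array([[0, 3]]), test_neg=np.array([[0, 2], [1, 3]]),
            n_cells=4, test_fraction=0.5, seed=0,
        )

    def test_uninformative_embeddings_give_half_auroc(self):
        rep = evaluate_embeddings(np.zeros((4, 3)), self._split())
        assert rep.auroc == pytest.approx(0.5)
        assert (rep.n_pos, rep.n_neg) == (2, 2)

    def test_empty_test_set_rejected(self):
        split = self._split()
        split.test_pos = np.empty((0, 2), int)
        with pytest.raises(ValueError, match="empty test"):
            evaluate_embeddings(np.zeros((4, 3)), split)
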