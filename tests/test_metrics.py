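import numpy as np
import pytest

from pairatac.metrics import (
    LabeledEmbedding,
    ari,
    asw_batch,
    asw_celltype,
    auroc_auprc,
    graph_connectivity,
    homogeneity_completeness,
    kbet_accept,
    lisi,
    nmi,
    pcc,
    pcc_matrix,
    v_measure,
)


class TestPcc:
    def test_self_correlation(self):
        x = np.array([1.0, 4.0, 2.0, 8.0])
        assert pcc(x, x) == pytest.approx(1.0)

    def test_anti_correlation(self):
        x = np.array([1.0, 4.0, 2.0, 8.0])
        assert pcc(x, -x) == pytest.approx(-1.0)

    def test_direct_formula_evaluation(self):
        # covariance-formula oracle for [1,2,3] vs [1,2,4]:
        # num = 3, den = sqrt(2 * 14/3) -> r = 3 / sqrt(28/3)
        assert pcc([1, 2, 3], [1, 2, 4]) == pytest.approx(3 / np.sqrt(2 * 14 / 3))

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            pcc([1, 1, 1], [1, 2, 3])


class TestPccMatrix:
    def test_identical_matrices(self):
        a = np.random.default_rng(0).normal(size=(5, 7))
        assert pcc_matrix(a, a.copy()) == pytest.approx(1.0)
        assert pcc_matrix(a, a.copy(), "peakwise") == pytest.approx(1.0)

    def test_single_row_reduces_to_pcc(self):
        a = np.array([[1.0, 2.0, 3.0]])
        b = np.array([[1.0, 2.0, 4.0]])
        assert pcc_matrix(a, b) == pytest.approx(pcc(a[0], b[0]))

    def test_mean_of_row_correlations(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(3, 6)), rng.normal(size=(3, 6))
        expected = np.mean([pcc(a[i], b[i]) for i in range(3)])
        assert pcc_matrix(a, b) == pytest.approx(expected)

    def test_zero_variance_rows_skipped(self):
        a = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        b = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert pcc_matrix(a, b) == pytest.approx(1.0)


class TestRocPr:
    def test_perfect_and_reversed(self):
        truth = np.array([0, 0, 1, 1])
        assert auroc_auprc([0.1, 0.2, 0.8, 0.9], truth)[0] == 1.0
        assert auroc_auprc([0.9, 0.8, 0.2, 0.1], truth)[0] == 0.0

    def test_six_point_toy_matches_threshold_enumeration(self):
        scores = np.array([0.9, 0.8, 0.6, 0.55, 0.3, 0.1])
        truth = np.array([1, 0, 1, 1, 0, 0])
        # brute force over all pairs (ties averaged): P(pos > neg)
        pos = scores[truth == 1]
        neg = scores[truth == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        expected_auroc = wins / (len(pos) * len(neg))
        # step-interpolated PR area: sum over recall steps of precision
        order = np.argsort(-scores)
        tp = fp = 0
        area = 0.0
        for i in order:
            if truth[i]:
                tp += 1
                area += tp / (tp + fp) / len(pos)
            else:
                fp += 1
        auroc, auprc = auroc_auprc(scores, truth)
        assert auroc == pytest.approx(expected_auroc)
        assert auprc == pytest.approx(area)

    def test_one_class_errors(self):
        with pytest.raises(ValueError, match="classes"):
            auroc_auprc([0.1, 0.9], [1, 1])


def all_partitions(n, max_blocks):
    """All set partitions of range(n) into at most max_blocks blocks."""
    out = []

    def rec(i, blocks):
        if i == n:
            out.append([list(b) for b in blocks])
            return
        for b in blocks:
            b.append(i)
            rec(i + 1, blocks)
            b.pop()
        if len(blocks) < max_blocks:
            blocks.append([i])
            rec(i + 1, blocks)
            blocks.pop()

    rec(0, [])
    return out


def labels_of(partition, n):
    lab = np.empty(n, dtype=int)
    for k, block in enumerate(partition):
        lab[block] = k
    return lab


class TestPartitionMetrics:
    def test_identical_and_permuted(self):
        a = np.array([0, 0, 1, 1, 2])
        b = np.array([5, 5, 9, 9, 1])  # same partition, renamed
        assert ari(a, a) == 1.0
        assert ari(a, b) == pytest.approx(1.0)
        assert nmi(a, b) == pytest.approx(1.0)
        h, c = homogeneity_completeness(a, b)
        assert (h, c) == (1.0, 1.0)

    def test_checkerboard(self):
        a = np.array([0, 0, 1, 1])
        b = np.array([0, 1, 0, 1])
        assert ari(a, b) == pytest.approx(-0.5)
        assert nmi(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_singleton_clusters_are_homogeneous(self):
        truth = np.array([0, 0, 1, 1])
        pred = np.arange(4)
        h, c = homogeneity_completeness(truth, pred)
        assert h == pytest.approx(1.0)
        assert c < 1.0

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            ari([0, 1], [0, 1, 2])


class TestVMeasure:
    def test_equal_components(self):
        assert v_measure(0.7, 0.7) == pytest.approx(0.7)

    def test_arithmetic(self):
        assert v_measure(1.0, 0.5) == pytest.approx(2 / 3)

    def test_equals_harmonic_mean_at_unit_weight(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            h, c = rng.random(2)
            assert v_measure(h, c, 1.0) == pytest.approx(2 * h * c / (h + c))

    def test_large_weight_limit_approaches_completeness(self):
        assert v_measure(0.9, 0.4, 1e9) == pytest.approx(0.4, rel=1e-6)

    def test_degenerate_zero(self):
        assert v_measure(0.0, 0.0) == 0.0


def two_far_clusters(n_each=5, sep=100.0, jitter=0.1, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(scale=jitter, size=(n_each, 2))
    b = rng.normal(scale=jitter, size=(n_each, 2)) + [sep, 0.0]
    coords = np.vstack([a, b])
    labels = np.array(["x"] * n_each + ["y"] * n_each)
    return coords, labels


class TestSilhouettes:
    def test_tight_far_clusters_near_one(self):
        coords, labels = two_far_clusters()
        assert asw_celltype(LabeledEmbedding(coords, labels)) > 0.99

    def test_six_point_toy_matches_manual_silhouette(self):
        coords = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        labels = np.array([0, 0, 0, 1, 1, 1])
        # manual per-point silhouette with euclidean distance
        sils = []
        for i in range(6):
            same = [j for j in range(6) if labels[j] == labels[i] and j != i]
            other = [j for j in range(6) if labels[j] != labels[i]]
            a = np.mean([abs(coords[i, 0] - coords[j, 0]) for j in same])
            b = np.mean([abs(coords[i, 0] - coords[j, 0]) for j in other])
            sils.append((b - a) / max(a, b))
        expected = (np.mean(sils) + 1) / 2
        out = asw_celltype(LabeledEmbedding(coords, labels))
        assert out == pytest.approx(expected)

    def test_single_label_errors(self):
        with pytest.raises(ValueError):
            asw_celltype(LabeledEmbedding(np.zeros((4, 2)), np.zeros(4)))

    def test_asw_batch_mixed_near_one(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(60, 2))
        labels = np.repeat(["a", "b"], 30)
        batches = np.tile(["b1", "b2"], 30)
        out = asw_batch(LabeledEmbedding(coords, labels, batches))
        assert out > 0.8

    def test_asw_batch_separated_near_zero(self):
        coords, batches = two_far_clusters(n_each=20)
        labels = np.full(40, "t")
        out = asw_batch(LabeledEmbedding(coords, labels, batches))
        assert out < 0.1

    def test_asw_batch_requires_batches(self):
        with pytest.raises(ValueError, match="batch"):
            asw_batch(LabeledEmbedding(np.zeros((4, 2)), np.zeros(4)))


class TestLisi:
    def test_single_category_neighborhoods(self):
        coords, batches = two_far_clusters(n_each=20)
        e = LabeledEmbedding(coords, np.full(40, "t"), batches, knn_k=5)
        assert lisi(e, "batch") == pytest.approx(0.0)
        # as a label metric the same geometry is perfect separation
        e2 = LabeledEmbedding(coords, batches, knn_k=5)
        assert lisi(e2, "label") == pytest.approx(1.0)

    def test_uniform_mixture_near_one(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(200, 2))
        batches = np.tile(["b1", "b2"], 100)
        e = LabeledEmbedding(coords, np.full(200, "t"), batches, knn_k=20)
        assert lisi(e, "batch") > 0.8

    def test_eight_point_toy_matches_simpson_oracle(self):
        coords = np.array(
            [[0.0], [0.1], [0.2], [0.3], [5.0], [5.1], [5.2], [5.3]])
        labels = np.array([0, 0, 1, 1, 0, 1, 0, 1])
        k = 3
        e = LabeledEmbedding(coords, labels, knn_k=k)
        # manual: each point's 3 nearest in its own tight quad
        from sklearn.neighbors import NearestNeighbors

        idx = NearestNeighbors(n_neighbors=k).fit(coords).kneighbors(
            return_distance=False)
        raws = []
        for i in range(8):
            comp = labels[idx[i]]
            p = np.bincount(comp, minlength=2) / k
            raws.append(1.0 / np.sum(p**2))
        expected = (2 - np.median(raws)) / (2 - 1)
        assert lisi(e, "label") == pytest.approx(expected)

    def test_k_too_large_errors(self):
        with pytest.raises(ValueError, match="knn_k"):
            lisi(LabeledEmbedding(np.zeros((4, 2)), [0, 0, 1, 1], knn_k=4))


class TestKbet:
    def test_single_batch_errors(self):
        e = LabeledEmbedding(np.zeros((10, 2)), np.zeros(10), np.zeros(10))
        with pytest.raises(ValueError, match="batches"):
            kbet_accept(e)

    def test_segregated_batches_rejected(self):
        coords, batches = two_far_clusters(n_each=30)
        e = LabeledEmbedding(coords, np.full(60, "t"), batches, knn_k=10)
        assert kbet_accept(e, n_samples=60, seed=0) < 0.05

    def test_null_calibration(self):
        # batches assigned i.i.d.: acceptance close to 1 - alpha
        rates = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            coords = rng.normal(size=(300, 3))
            batches = rng.choice(["b1", "b2"], size=300)
            e = LabeledEmbedding(coords, np.full(300, "t"), batches, knn_k=15)
            rates.append(kbet_accept(e, n_samples=150, alpha=0.05, seed=seed))
        assert 0.90 <= np.mean(rates) <= 1.0


class TestGraphConnectivity:
    def test_connected_label_subgraphs_score_one(self):
        coords, labels = two_far_clusters(n_each=10)
        e = LabeledEmbedding(coords, labels, knn_k=5)
        assert graph_connectivity(e) == 1.0

    def test_split_label_scores_fraction(self):
        # label A: path of 3 near origin + 1 isolated far beyond B's cluster
        coords = np.array(
            [[0.0, 0], [1.0, 0], [2.0, 0], [200.0, 0],
             [50.0, 0], [51.0, 0], [52.0, 0], [53.0, 0]])
        labels = np.array(["A", "A", "A", "A", "B", "B", "B", "B"])
        e = LabeledEmbedding(coords, labels, knn_k=2)
        assert graph_connectivity(e) == pytest.approx((0.75 + 1.0) / 2)

    def test_singleton_label_counts_as_connected(self):
        coords = np.array([[0.0, 0], [1.0, 0], [2.0, 0], [100.0, 0]])
        labels = np.array(["A", "A", "A", "B"])
        e = LabeledEmbedding(coords, labels, knn_k=2)
        assert graph_connectivity(e) == 1.0


class TestRelabelInvariance:
    @pytest.mark.parametrize("metric", [ari, nmi])
    def test_partition_metrics(self, metric):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 3, size=40)
        b = rng.integers(0, 4, size=40)
        remap = {0: 7, 1: 3, 2: 11, 3: 0}
        b2 = np.array([remap[x] for x in b])
        assert metric(a, b) == pytest.approx(metric(a, b2))
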