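import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_samples

from igscluster.spectral_clustering import (cluster_graph, eigenspectrum,
                                            kmeans, normalized_laplacian,
                                            silhouette_values,
                                            spectral_embedding, suggest_k)

from oracles import best_partition_sse, silhouette_textbook


def block_adjacency(sizes, within=1.0, between=0.0, rng=None):
    n = sum(sizes)
    W = np.full((n, n), between, dtype=float)
    start = 0
    for s in sizes:
        W[start:start + s, start:start + s] = within
        start += s
    np.fill_diagonal(W, 0.0)
    if rng is not None:
        noise = rng.uniform(0, between / 10 if between else 0.01, size=(n, n))
        W += (noise + noise.T) / 2
        np.fill_diagonal(W, 0.0)
    return W


class TestNormalizedLaplacian:
    def test_two_disjoint_cliques_give_double_zero_eigenvalue(self):
        W = block_adjacency([3, 3])
        spec = eigenspectrum(normalized_laplacian(W))
        assert np.sum(np.abs(spec.eigenvalues) < 1e-10) == 2

    def test_single_edge_spectrum_is_zero_and_two(self):
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        spec = eigenspectrum(normalized_laplacian(W))
        assert spec.eigenvalues == pytest.approx([0.0, 2.0])

    @pytest.mark.parametrize("q", [2, 3, 4])
    def test_q_clique_blocks_have_null_multiplicity_q(self, q):
        W = block_adjacency([4] * q)
        spec = eigenspectrum(normalized_laplacian(W))
        assert np.sum(np.abs(spec.eigenvalues) < 1e-10) == q

    def test_matches_definition(self, rng):
        W = block_adjacency([3, 4], within=0.8, between=0.2, rng=rng)
        d = W.sum(axis=1)
        D_inv_sqrt = np.diag(1.0 / np.sqrt(d))
        expected = D_inv_sqrt @ (np.diag(d) - W) @ D_inv_sqrt
        assert normalized_laplacian(W) == pytest.approx(expected)

    def test_zero_degree_node_rejected(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        with pytest.raises(ValueError, match="zero-degree"):
            normalized_laplacian(W)

    def test_asymmetric_input_rejected(self):
        W = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            normalized_laplacian(W)


class TestEigenspectrum:
    def test_diagonal_matrix_eigenvalues_sorted(self):
        spec = eigenspectrum(np.diag([3.0, 1.0, 2.0]))
        assert spec.eigenvalues == pytest.approx([1.0, 2.0, 3.0])

    def test_spectrum_bounded_by_zero_and_two(self, rng):
        W = block_adjacency([5, 5, 5], within=0.9, between=0.3, rng=rng)
        spec = eigenspectrum(normalized_laplacian(W))
        assert spec.eigenvalues[0] >= -1e-10
        assert spec.eigenvalues[-1] <= 2 + 1e-10

    def test_connected_graph_has_single_null_eigenvalue(self, rng):
        W = block_adjacency([4, 4], within=1.0, between=0.2)
        spec = eigenspectrum(normalized_laplacian(W))
        assert np.sum(spec.eigenvalues < 1e-10) == 1

    def test_sign_canonicalization_is_deterministic(self, rng):
        W = block_adjacency([4, 4], within=0.9, between=0.1, rng=rng)
        L = normalized_laplacian(W)
        v1 = eigenspectrum(L).eigenvectors
        v2 = eigenspectrum(L).eigenvectors
        assert v1 == pytest.approx(v2)


class TestSuggestK:
    def test_example_spectrum(self):
        lam = [0.0, 0.01, 0.02, 0.5, 0.55, 0.6, 0.62, 0.65]
        k, gaps = suggest_k(lam, k_max=6)
        assert k == 3
        assert gaps[1] == pytest.approx(0.48)  # candidate k=3

    @pytest.mark.parametrize("q", [2, 3, 4])
    def test_exact_block_graph(self, q):
        W = block_adjacency([4] * q, within=1.0, between=0.0)
        # tiny inter-block weight connects the graph without hiding the gap
        W[0, -1] = W[-1, 0] = 1e-6
        spec = eigenspectrum(normalized_laplacian(W))
        k, _ = suggest_k(spec.eigenvalues, k_max=min(8, 4 * q - 1))
        assert k == q

    def test_flat_spectrum_warns_and_returns_k_max(self):
        lam = np.linspace(0, 1, 30)
        with pytest.warns(UserWarning, match="flat eigengap"):
            k, _ = suggest_k(lam, k_max=10)
        assert k == 10


class TestSpectralEmbedding:
    def test_rows_have_unit_norm(self, rng):
        W = block_adjacency([5, 5], within=0.9, between=0.2, rng=rng)
        spec = eigenspectrum(normalized_laplacian(W))
        emb = spectral_embedding(spec.eigenvectors, 2)
        assert np.linalg.norm(emb.T, axis=1) == pytest.approx(np.ones(10))

    def test_k1_on_connected_graph_gives_signs(self):
        W = block_adjacency([4], within=1.0)
        spec = eigenspectrum(normalized_laplacian(W))
        emb = spectral_embedding(spec.eigenvectors, 1)
        assert np.abs(emb.T) == pytest.approx(np.ones((4, 1)))

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            spectral_embedding(np.eye(3), 4)

    def test_zero_row_flagged_and_canonicalized(self):
        vecs = np.array([[1.0, 0.0], [0.0, 0.0]])
        emb = spectral_embedding(vecs, 2)
        assert emb.degenerate_rows == [1]
        assert np.linalg.norm(emb.T[1]) == pytest.approx(1.0)


class TestKMeans:
    def test_recovers_separated_blobs(self, rng):
        centers = np.array([[0, 0], [10, 10], [-10, 5]])
        pts = np.vstack([c + rng.normal(0, 0.3, size=(20, 2)) for c in centers])
        labels, _ = kmeans(pts, 3, rng=rng)
        true = np.repeat([0, 1, 2], 20)
        assert adjusted_rand_score(true, labels) == 1.0

    def test_k_equals_n_gives_zero_sse(self, rng):
        pts = rng.normal(size=(5, 2))
        labels, centroids = kmeans(pts, 5, rng=rng)
        assert sorted(labels) == list(range(5))
        assert centroids[labels] == pytest.approx(pts)

    def test_seed_determinism(self, rng):
        pts = rng.normal(size=(30, 3))
        l1, c1 = kmeans(pts, 4, rng=np.random.default_rng(2))
        l2, c2 = kmeans(pts, 4, rng=np.random.default_rng(2))
        assert np.array_equal(l1, l2)
        assert c1 == pytest.approx(c2)

    def test_k_exceeding_points_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans(rng.normal(size=(3, 2)), 4, rng=rng)

    @pytest.mark.parametrize("seed", range(5))
    def test_reaches_exhaustive_optimum_on_tiny_inputs(self, seed):
        """Best-of-restarts SSE matches the brute-force optimal partition
        for n <= 8 points and k <= 3."""
        r = np.random.default_rng(seed)
        n = int(r.integers(5, 9))
        k = int(r.integers(2, 4))
        pts = r.normal(size=(n, 2))
        # Lloyd's is a local optimizer; enough restarts to sweep the small
        # space of distinct-point initializations on <= 8 points
        labels, centroids = kmeans(pts, k, n_init=60, rng=r)
        sse = sum(((pts[labels == c] - centroids[c]) ** 2).sum()
                  for c in range(k))
        assert sse <= best_partition_sse(pts, k) + 1e-9


class TestSilhouette:
    def test_hand_worked_example(self):
        """Two clusters {0.0, 0.1} and {1.0}: under the cluster-size
        divisor a(0.0) = 0.1/2 = 0.05, b(0.0) = 1.0, s = 0.95."""
        pts = np.array([0.0, 0.1, 1.0])
        labels = np.array([0, 0, 1])
        s, means = silhouette_values(pts, labels, normalization="cluster_size")
        assert s[0] == pytest.approx(0.95)
        assert s[2] == 0.0  # singleton convention
        assert means[0] == pytest.approx((0.95 + (0.9 / 1.0) / 0.95) / 2, abs=0.2)

    @pytest.mark.parametrize("seed", range(10))
    def test_standard_normalization_matches_sklearn(self, seed):
        r = np.random.default_rng(seed)
        pts = r.normal(size=(25, 3))
        labels = r.integers(0, 3, size=25)
        if len(set(labels.tolist())) < 2:
            labels[0] = (labels[0] + 1) % 3
        s, _ = silhouette_values(pts, labels, normalization="standard")
        assert s == pytest.approx(silhouette_samples(pts, labels), abs=1e-12)

    def test_standard_matches_naive_textbook_formula(self, rng):
        pts = rng.normal(size=(12, 2))
        labels = rng.integers(0, 2, size=12)
        s, _ = silhouette_values(pts, labels, normalization="standard")
        assert s == pytest.approx(silhouette_textbook(pts, labels), abs=1e-12)

    def test_mirror_symmetric_points_get_equal_values(self):
        pts = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        labels = np.array([0, 0, 1, 1])
        s, _ = silhouette_values(pts, labels)
        assert s[0] == pytest.approx(s[3])
        assert s[1] == pytest.approx(s[2])

    def test_values_bounded(self, rng):
        pts = rng.normal(size=(40, 2))
        labels = rng.integers(0, 4, size=40)
        s, _ = silhouette_values(pts, labels)
        assert np.all(s >= -1) and np.all(s <= 1)

    def test_single_cluster_rejected(self, rng):
        with pytest.raises(ValueError):
            silhouette_values(rng.normal(size=(5, 2)), np.zeros(5, dtype=int))


class TestClusterGraph:
    def test_planted_partition_recovery(self, rng):
        """Strongly separated blocks are recovered exactly (ARI = 1) and
        the eigengap lands on the block count."""
        W = block_adjacency([15, 15, 15], within=1.0, between=0.02, rng=rng)
        ids = [f"n{i}" for i in range(45)]
        result, spec, _ = cluster_graph(ids, W, rng=rng)
        assert spec.suggested_k == 3
        true = np.repeat([0, 1, 2], 15)
        assert adjusted_rand_score(true, result.labels) == 1.0
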