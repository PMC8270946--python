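"""Graph construction (MST/RMST), Laplacian eigenmaps, PCA and the
intrinsic-dimension plateau estimate."""

import itertools

import networkx as nx
import numpy as np
import pytest

from imanifold.datatypes import CCDMatrix, DistanceMatrix
from imanifold.manifold import (
    RMSTParams,
    ccd_to_distance,
    estimate_intrinsic_dimension,
    graph_laplacian,
    knn_distance,
    laplacian_eigenmaps,
    minimum_spanning_tree,
    pca_embedding,
    rmst,
)


def random_distance_matrix(n, seed):
    rng = np.random.default_rng(seed)
    x = rng.uniform(size=(n, 3))
    d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
    return d


class TestCCDToDistance:
    def test_extremes_and_worked_value(self):
        m = np.array(
            [
                [1.0, 1.0, -1.0],
                [1.0, 1.0, 0.7887],
                [-1.0, 0.7887, 1.0],
            ]
        )
        d = ccd_to_distance(CCDMatrix(matrix=m)).matrix
        assert d[0, 1] == pytest.approx(0.0)
        assert d[0, 2] == pytest.approx(2.0)
        assert d[1, 2] == pytest.approx(0.2113, abs=1e-4)
        assert np.all(np.diag(d) == 0.0)


class TestMST:
    def test_three_node_brute_force(self):
        d = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        edges = {tuple(e) for e in minimum_spanning_tree(d)}
        assert edges == {(0, 1), (0, 2)}
        # brute force over the 3 possible spanning trees
        best = min(
            [[(0, 1), (0, 2)], [(0, 1), (1, 2)], [(0, 2), (1, 2)]],
            key=lambda t: sum(d[i, j] for i, j in t),
        )
        assert edges == set(best)

    def test_two_nodes(self):
        d = np.array([[0.0, 0.4], [0.4, 0.0]])
        assert minimum_spanning_tree(d).tolist() == [[0, 1]]

    def test_chain_distances_give_chain(self):
        # consecutive distances smallest => the path graph is the unique MST
        x = np.array([0.0, 1.0, 2.1, 3.3, 4.6])
        d = np.abs(x[:, None] - x[None, :])
        edges = {tuple(e) for e in minimum_spanning_tree(d)}
        assert edges == {(0, 1), (1, 2), (2, 3), (3, 4)}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_total_weight_matches_networkx(self, seed):
        d = random_distance_matrix(15, seed)
        ours = minimum_spanning_tree(d)
        w_ours = sum(d[i, j] for i, j in ours)
        g = nx.from_numpy_array(d)
        w_nx = sum(
            data["weight"] for _, _, data in nx.minimum_spanning_edges(g, data=True)
        )
        assert w_ours == pytest.approx(w_nx, abs=1e-12)

    def test_nonfinite_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.inf
        with pytest.raises(ValueError, match="finite"):
            minimum_spanning_tree(d)


def brute_force_rmst(d, gamma, k_n, k_local):
    """Exhaustive oracle: MST path max weights by explicit path search,
    relaxation condition applied per pair in ascending distance."""
    n = d.shape[0]
    mst = {tuple(e) for e in minimum_spanning_tree(d)}
    g = nx.Graph(list(mst))
    dk = np.sort(d + np.diag([np.inf] * n), axis=1)[:, k_local - 1]
    candidates = []
    for i, j in itertools.combinations(range(n), 2):
        if (i, j) in mst:
            continue
        path = nx.shortest_path(g, i, j)
        mw = max(d[a, b] for a, b in zip(path[:-1], path[1:]))
        if mw + gamma * (dk[i] + dk[j]) > d[i, j]:
            candidates.append((d[i, j], i, j))
    added = {k: 0 for k in range(n)}
    extra = set()
    for _, i, j in sorted(candidates):
        if added[i] < k_n and added[j] < k_n:
            extra.add((i, j))
            added[i] += 1
            added[j] += 1
    return mst, extra


class TestRMST:
    @pytest.mark.parametrize("seed", range(20))
    def test_gamma_zero_reduces_to_mst(self, seed):
        d = random_distance_matrix(25, seed)
        g = rmst(d, RMSTParams(gamma=0.0))
        assert g.extra_edges.size == 0
        assert g.n_edges == 24

    def test_huge_gamma_saturates_degree_cap(self):
        d = random_distance_matrix(5, 3)
        g = rmst(d, RMSTParams(gamma=1e6, k_n=10))
        assert g.n_edges > 4  # strictly more than the MST
        assert g.n_edges == 10  # complete graph on 5 nodes

    @pytest.mark.parametrize("seed", [0, 5, 9])
    def test_matches_brute_force_oracle_on_six_nodes(self, seed):
        d = random_distance_matrix(6, seed)
        g = rmst(d, RMSTParams(gamma=3.0, k_n=5, k_local=1))
        mst_o, extra_o = brute_force_rmst(d, 3.0, 5, 1)
        assert {tuple(e) for e in g.mst_edges} == mst_o
        assert {tuple(e) for e in g.extra_edges} == extra_o

    @pytest.mark.parametrize("seed", range(20))
    def test_edge_count_monotone_in_gamma(self, seed):
        d = random_distance_matrix(18, 100 + seed)
        counts = [
            rmst(d, RMSTParams(gamma=g, k_n=5)).n_edges
            for g in (0.0, 0.5, 1.0, 3.0, 10.0)
        ]
        assert counts == sorted(counts)

    def test_rmst_contains_mst(self):
        d = random_distance_matrix(30, 7)
        g = rmst(d, RMSTParams())
        mst = {tuple(e) for e in minimum_spanning_tree(d)}
        assert mst <= {tuple(e) for e in g.edges}

    def test_relaxation_additions_respect_cap(self):
        d = random_distance_matrix(40, 2)
        k_n = 3
        g = rmst(d, RMSTParams(gamma=10.0, k_n=k_n))
        deg = np.zeros(40, dtype=int)
        for i, j in g.extra_edges:
            deg[i] += 1
            deg[j] += 1
        assert deg.max() <= k_n


class TestGraphLaplacian:
    def test_single_edge(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        L = graph_laplacian(rmst(d, RMSTParams(gamma=0.0)))
        assert np.allclose(L, [[1, -1], [-1, 1]])

    def test_path_p3_spectrum(self):
        d = np.array([[0, 1, 5], [1, 0, 1], [5, 1, 0]], dtype=float)
        L = graph_laplacian(rmst(d, RMSTParams(gamma=0.0)))
        vals = np.linalg.eigvalsh(L)
        assert np.allclose(vals, [0.0, 1.0, 3.0], atol=1e-10)

    def test_rows_sum_to_zero_and_psd(self):
        d = random_distance_matrix(12, 4)
        for weighting in ("binary", "similarity"):
            L = graph_laplacian(rmst(d, RMSTParams()), weighting)
            assert np.allclose(L @ np.ones(12), 0.0, atol=1e-12)
            assert np.linalg.eigvalsh(L).min() > -1e-10


class TestLaplacianEigenmaps:
    def test_path_graph_closed_form(self):
        """P_n Laplacian: lambda_k = 2 - 2 cos(pi k / n), eigenvector
        entries cos(pi k (i + 1/2) / n)."""
        n = 8
        A = np.zeros((n, n))
        for i in range(n - 1):
            A[i, i + 1] = A[i + 1, i] = 1.0
        L = np.diag(A.sum(1)) - A
        emb = laplacian_eigenmaps(L, 3)
        for k in (1, 2, 3):
            lam = 2 - 2 * np.cos(np.pi * k / n)
            assert emb.eigenvalues[k - 1] == pytest.approx(lam, abs=1e-8)
            v = np.cos(np.pi * k * (np.arange(n) + 0.5) / n)
            v /= np.linalg.norm(v)
            got = emb.coords[:, k - 1]
            agreement = abs(np.dot(got, v))
            assert agreement == pytest.approx(1.0, abs=1e-8)

    def test_complete_graph_spectrum(self):
        n = 5
        A = np.ones((n, n)) - np.eye(n)
        L = np.diag(A.sum(1)) - A
        emb = laplacian_eigenmaps(L, n - 1)
        assert np.allclose(emb.eigenvalues, 5.0, atol=1e-8)

    def test_sign_convention_largest_entry_positive(self):
        d = random_distance_matrix(10, 8)
        emb = laplacian_eigenmaps(graph_laplacian(rmst(d, RMSTParams())), 3)
        for c in range(3):
            col = emb.coords[:, c]
            assert col[np.argmax(np.abs(col))] > 0

    def test_columns_orthogonal_to_constant_and_each_other(self):
        d = random_distance_matrix(20, 9)
        emb = laplacian_eigenmaps(graph_laplacian(rmst(d, RMSTParams())), 4)
        gram = emb.coords.T @ emb.coords
        assert np.allclose(gram, np.diag(np.diag(gram)), atol=1e-8)
        assert np.allclose(emb.coords.sum(axis=0), 0.0, atol=1e-8)

    def test_disconnected_graph_rejected(self):
        L = np.array(
            [[1, -1, 0, 0], [-1, 1, 0, 0], [0, 0, 1, -1], [0, 0, -1, 1]], float
        )
        with pytest.raises(ValueError, match="disconnected"):
            laplacian_eigenmaps(L, 2)

    def test_dimension_bounds(self):
        L = np.array([[1.0, -1.0], [-1.0, 1.0]])
        with pytest.raises(ValueError):
            laplacian_eigenmaps(L, 2)


class TestPCAEmbedding:
    def test_recovers_planted_two_dim_structure(self, rng):
        latent = rng.standard_normal((200, 2))
        basis, _ = np.linalg.qr(rng.standard_normal((5, 2)))
        X = latent @ basis.T
        emb = pca_embedding(X, 2)
        # recovered scores equal the centred latent coordinates up to
        # rotation/sign (PCA centres the features before decomposition)
        latent_c = latent - latent.mean(axis=0)
        M = np.linalg.lstsq(emb.coords, latent_c, rcond=None)[0]
        resid = np.linalg.norm(emb.coords @ M - latent_c)
        assert resid < 1e-6
        assert np.allclose(M.T @ M, np.eye(2), atol=1e-6)

    def test_rank_one_data_single_component(self, rng):
        u = rng.standard_normal((50, 1))
        X = u @ np.array([[1.0, 2.0, -1.0]])
        emb = pca_embedding(X, 3)
        total = emb.eigenvalues.sum()
        assert emb.eigenvalues[0] / total == pytest.approx(1.0, abs=1e-10)

    def test_scores_match_covariance_eigendecomposition(self):
        X = np.array([[1.0, 2.0, 0.0], [0.0, 1.0, 1.0], [2.0, 0.0, 1.0], [1.0, 1.0, 2.0]])
        emb = pca_embedding(X, 3)
        Xc = X - X.mean(0)
        vals, vecs = np.linalg.eigh(Xc.T @ Xc / 3)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        assert np.allclose(emb.eigenvalues, vals, atol=1e-10)
        scores = Xc @ vecs
        assert np.allclose(np.abs(emb.coords), np.abs(scores), atol=1e-10)

    def test_variance_trace_identity(self, rng):
        X = rng.standard_normal((60, 8))
        d = 4
        emb = pca_embedding(X, d)
        # variance captured by scores equals the top-d eigenvalue sum
        assert emb.coords.var(axis=0, ddof=1).sum() == pytest.approx(
            emb.eigenvalues.sum(), abs=1e-8
        )

    def test_d_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            pca_embedding(rng.standard_normal((10, 3)), 4)


class TestIntrinsicDimension:
    def test_identical_accuracies_give_smallest_dim(self, rng):
        acc = {d: 0.8 + 0.001 * rng.standard_normal(10) for d in range(1, 6)}
        flat = {d: acc[1] for d in range(1, 6)}
        res = estimate_intrinsic_dimension(flat)
        assert res.dimension == 1 and res.plateau_found

    def test_increase_then_plateau_detected_at_three(self, rng):
        acc = {}
        for d in range(1, 7):
            level = {1: 0.4, 2: 0.6, 3: 0.85}.get(d, 0.85)
            acc[d] = level + 0.01 * rng.standard_normal(18)
        res = estimate_intrinsic_dimension(acc)
        assert res.dimension == 3 and res.plateau_found
        # oracle: pairwise rank-sum on the constructed samples
        from imanifold.stats import rank_sum_test

        assert rank_sum_test(acc[4], acc[3]) > 0.05
        assert rank_sum_test(acc[3], acc[2]) < 0.001

    def test_single_dimension_returned_as_is(self):
        res = estimate_intrinsic_dimension({4: np.array([0.7, 0.71, 0.72])})
        assert res.dimension == 4 and res.plateau_found

    def test_no_plateau_returns_max_with_flag(self):
        acc = {d: np.linspace(0.1 * d, 0.1 * d + 0.01, 8) for d in range(1, 5)}
        with pytest.warns(UserWarning, match="plateau"):
            res = estimate_intrinsic_dimension(acc)
        assert res.dimension == 4 and not res.plateau_found


def test_knn_distance_simple():
    d = np.array([[0, 1, 4], [1, 0, 2], [4, 2, 0]], dtype=float)
    assert knn_distance(d, 1).tolist() == [1, 1, 2]
    assert knn_distance(d, 2).tolist() == [4, 2, 4]
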