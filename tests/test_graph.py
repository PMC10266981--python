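"""Graph-Laplacian bases, thresholding and the exponential distance rule."""

import numpy as np
import pytest
import scipy.sparse as sp

import brainmodes as bm
from brainmodes.graph import n_edges, merge_adjacency


def toy_connectome(n, weights):
    """Symmetric connectome from {(i, j): w} dict."""
    W = np.zeros((n, n))
    for (i, j), w in weights.items():
        W[i, j] = W[j, i] = w
    return bm.SparseConnectome(sp.csr_matrix(W))


class TestLocalAdjacency:
    def test_single_triangle(self):
        mesh = bm.TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
        A = bm.local_adjacency(mesh).toarray()
        assert np.array_equal(A, 1 - np.eye(3))

    def test_icosahedron_valence_five(self):
        A = bm.local_adjacency(bm.make_icosphere(0, 1.0))
        assert np.all(np.asarray(A.sum(axis=1)).ravel() == 5)

    def test_edge_count_matches_brute_force(self, sphere2):
        A = bm.local_adjacency(sphere2)
        edges = set()
        for a, b, c in sphere2.faces:
            for i, j in ((a, b), (b, c), (c, a)):
                edges.add((min(i, j), max(i, j)))
        assert n_edges(A) == len(edges)


class TestThresholding:
    def test_fourfold_keeps_largest(self):
        rng = np.random.default_rng(0)
        iu, ju = np.triu_indices(6, k=1)
        w = rng.permutation(len(iu)) + 1.0  # distinct weights
        W = toy_connectome(6, {(i, j): x for i, j, x in zip(iu, ju, w)})
        A_local = sp.csr_matrix(
            (np.ones(6), ([0, 1, 2, 1, 2, 3], [1, 0, 3, 2, 1, 2])), shape=(6, 6))
        out = bm.threshold_fourfold(W, A_local)
        assert n_edges(out) == 12
        # oracle: the 12 largest by brute-force sorting
        kept = {(i, j) for i, j in zip(*sp.triu(out, k=1).nonzero())}
        order = sorted(zip(w, iu, ju), reverse=True)[:12]
        assert kept == {(i, j) for _, i, j in order}

    def test_fourfold_identity_on_exact_binary(self):
        pairs = [(0, 1), (0, 2), (1, 2), (3, 4)]
        W = toy_connectome(5, {p: 1.0 for p in pairs})
        A_local = sp.csr_matrix((np.ones(2), ([0, 1], [1, 0])), shape=(5, 5))
        out = bm.threshold_fourfold(W, A_local)
        assert np.array_equal(out.toarray(), W.weights.toarray())

    def test_all_equal_ties_deterministic(self):
        iu, ju = np.triu_indices(6, k=1)
        W = toy_connectome(6, {(i, j): 1.0 for i, j in zip(iu, ju)})
        A_local = sp.csr_matrix((np.ones(2), ([0, 1], [1, 0])), shape=(6, 6))
        out1 = bm.threshold_fourfold(W, A_local)
        out2 = bm.threshold_fourfold(W, A_local)
        assert n_edges(out1) == 4
        assert np.array_equal(out1.toarray(), out2.toarray())
        # lexicographic tie-break keeps the smallest index pairs
        kept = sorted(zip(*sp.triu(out1, k=1).nonzero()))
        assert kept == [(0, 1), (0, 2), (0, 3), (0, 4)]

    def test_fourfold_insufficient_weights(self):
        W = toy_connectome(5, {(0, 1): 1.0})
        A_local = sp.csr_matrix((np.ones(2), ([0, 1], [1, 0])), shape=(5, 5))
        with pytest.raises(ValueError, match="available"):
            bm.threshold_fourfold(W, A_local)

    def test_density_counting(self):
        rng = np.random.default_rng(1)
        iu, ju = np.triu_indices(5, k=1)
        W = toy_connectome(5, {(i, j): rng.random() + 0.1
                               for i, j in zip(iu, ju)})
        out = bm.threshold_to_density(W, 0.4)
        assert n_edges(out) == 4
        assert bm.connection_density(out) == pytest.approx(0.4)

    def test_density_identity_and_tolerance(self):
        pairs = [(0, 1), (1, 2), (2, 3)]
        W = toy_connectome(6, {p: 1.0 for p in pairs})
        d = bm.connection_density(W.weights)
        out = bm.threshold_to_density(W, d)
        assert np.array_equal(out.toarray(), W.weights.toarray())
        V = 6
        assert abs(bm.connection_density(out) - d) <= 1.0 / (V * (V - 1) / 2)

    def test_merged_contains_local(self, sphere2, rng):
        A_local = bm.local_adjacency(sphere2)
        D = bm.pairwise_distance(sphere2)
        W, _ = bm.synth_connectome(sphere2, alpha=1.2, seed=0)
        A_conn = bm.threshold_fourfold(W, A_local)
        A_C = merge_adjacency(A_local, A_conn)
        # superset property: every local edge survives the merge
        assert (A_C.multiply(A_local) - A_local).nnz == 0


class TestEDR:
    def test_exact_recovery_noise_free(self, sphere2):
        D = bm.pairwise_distance(bm.TriangleMesh(sphere2.vertices * 30, sphere2.faces))
        iu, ju = np.triu_indices(len(D), k=1)
        w = np.exp(-0.12 * D[iu, ju])
        W = bm.SparseConnectome(sp.csr_matrix(
            (np.concatenate([w, w]), (np.concatenate([iu, ju]),
                                      np.concatenate([ju, iu]))), shape=D.shape))
        model = bm.fit_edr_alpha(W, D)
        assert model.alpha == pytest.approx(0.12, abs=5e-5)

    def test_recovery_under_noise(self, sphere2, rng):
        D = bm.pairwise_distance(bm.TriangleMesh(sphere2.vertices * 10, sphere2.faces))
        iu, ju = np.triu_indices(len(D), k=1)
        w = np.exp(-0.5 * D[iu, ju]) * (1 + 0.05 * rng.uniform(-1, 1, len(iu)))
        W = bm.SparseConnectome(sp.csr_matrix(
            (np.concatenate([w, w]), (np.concatenate([iu, ju]),
                                      np.concatenate([ju, iu]))), shape=D.shape))
        model = bm.fit_edr_alpha(W, D)
        assert abs(model.alpha - 0.5) / 0.5 < 0.05

    def test_flat_weights_flagged(self, sphere2):
        D = bm.pairwise_distance(sphere2)
        iu, ju = np.triu_indices(len(D), k=1)
        w = np.ones(len(iu))
        W = bm.SparseConnectome(sp.csr_matrix(
            (np.concatenate([w, w]), (np.concatenate([iu, ju]),
                                      np.concatenate([ju, iu]))), shape=D.shape))
        model = bm.fit_edr_alpha(W, D)
        assert model.diagnostics["alpha_near_zero"]

    def test_generate_edr_limits(self):
        D = np.array([[0, 1.0], [1.0, 0]])
        assert bm.generate_edr(D, alpha=1e6, seed=0).nnz == 0
        D0 = np.zeros((4, 4))
        A = bm.generate_edr(D0, alpha=1.0, seed=0)
        assert n_edges(A) == 6  # p = 1 everywhere off-diagonal

    def test_generate_edr_density_matches_expectation(self, sphere2):
        D = bm.pairwise_distance(sphere2)
        iu, ju = np.triu_indices(len(D), k=1)
        p = np.exp(-2.0 * D[iu, ju])
        expect = p.mean()
        se = np.sqrt(p.var() / len(p) + expect * (1 - expect) / len(p))
        densities = [bm.connection_density(bm.generate_edr(D, 2.0, seed=s))
                     for s in range(20)]
        assert abs(np.mean(densities) - expect) < 3 * se


class TestLaplacianAndModes:
    def path3(self):
        A = sp.csr_matrix((np.ones(4), ([0, 1, 1, 2], [1, 0, 2, 1])), shape=(3, 3))
        return A

    def test_path_graph_spectra(self):
        L = bm.graph_laplacian(self.path3())
        np.testing.assert_allclose(np.linalg.eigvalsh(L.toarray()), [0, 1, 3],
                                   atol=1e-12)
        Ln = bm.graph_laplacian(self.path3(), normalized=True)
        np.testing.assert_allclose(np.linalg.eigvalsh(Ln.toarray()), [0, 1, 2],
                                   atol=1e-12)

    def test_row_sums_zero(self, sphere2):
        L = bm.graph_laplacian(bm.local_adjacency(sphere2))
        assert np.abs(L.sum(axis=1)).max() < 1e-12

    def test_isolated_vertex_error(self):
        A = sp.csr_matrix((np.ones(2), ([0, 1], [1, 0])), shape=(3, 3))
        with pytest.raises(ValueError, match="isolated"):
            bm.graph_laplacian(A, normalized=True)

    def test_ring_graph_closed_form(self):
        n = 12
        i = np.arange(n)
        A = sp.csr_matrix((np.ones(2 * n), (np.concatenate([i, (i + 1) % n]),
                                            np.concatenate([(i + 1) % n, i]))),
                          shape=(n, n))
        basis = bm.solve_graph_modes(bm.graph_laplacian(A), n - 1)
        expect = np.sort(2 - 2 * np.cos(2 * np.pi * np.arange(n) / n))[:n - 1]
        np.testing.assert_allclose(basis.eigenvalues, expect, atol=1e-8)

    def test_connectivity_null_space(self):
        # connected graph: one ~0 eigenvalue; two cliques: two
        block = np.ones((3, 3)) - np.eye(3)
        two = sp.csr_matrix(np.block([[block, np.zeros((3, 3))],
                                      [np.zeros((3, 3)), block]]))
        basis = bm.solve_graph_modes(bm.graph_laplacian(two), 4)
        assert np.sum(np.abs(basis.eigenvalues) < 1e-8) == 2
        one = bm.solve_graph_modes(bm.graph_laplacian(self.path3()), 2)
        assert np.sum(np.abs(one.eigenvalues) < 1e-8) == 1

    def test_normalized_first_mode_proportional_to_sqrt_degree(self, sphere2):
        A = bm.local_adjacency(sphere2)
        basis = bm.solve_graph_modes(bm.graph_laplacian(A, normalized=True), 5)
        deg = np.asarray(A.sum(axis=1)).ravel()
        v = basis.modes[:, 0]
        expected = np.sqrt(deg) / np.linalg.norm(np.sqrt(deg))
        assert min(np.abs(v - expected).max(), np.abs(v + expected).max()) < 1e-6

    def test_connection_density_counts(self):
        full = sp.csr_matrix(np.ones((5, 5)) - np.eye(5))
        assert bm.connection_density(full) == 1.0
        assert bm.connection_density(sp.csr_matrix((5, 5))) == 0.0
        rng = np.random.default_rng(3)
        iu, ju = np.triu_indices(6, k=1)
        pick = rng.choice(len(iu), 7, replace=False)
        A = sp.csr_matrix((np.ones(7), (iu[pick], ju[pick])), shape=(6, 6))
        assert bm.connection_density(A + A.T) == pytest.approx(7 / 15)


class TestConnectomeIO:
    def test_round_trip(self, sphere2, tmp_path):
        W, _ = bm.synth_connectome(sphere2, alpha=1.5, seed=4, weight_jitter=0.05)
        path = tmp_path / "conn.txt"
        bm.save_connectome(str(path), W)
        back = bm.load_connectome(str(path))
        assert (abs(back.weights - W.weights) > 1e-12).nnz == 0
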