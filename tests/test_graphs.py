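"""Graph construction, Laplacian and centrality checks against
brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from netrl.graphs import (
    WeightedGraph,
    adjacency_from_coefficients,
    adjacency_from_correlation,
    betweenness,
    binarize,
    centrality_scores,
    hubness,
    normalized_laplacian,
)


def brute_force_betweenness(A: np.ndarray) -> np.ndarray:
    """Exhaustive shortest-path enumeration on a small binary adjacency."""
    A = (np.maximum(A, A.T) > 0).astype(int)
    n = A.shape[0]
    if n < 3:
        return np.zeros(n)

    def all_shortest_paths(s, t):
        # breadth-first enumeration of every shortest s-t path
        paths, frontier = [], [[s]]
        while frontier and not paths:
            nxt = []
            for path in frontier:
                last = path[-1]
                for v in range(n):
                    if A[last, v] and v not in path:
                        if v == t:
                            paths.append(path + [v])
                        else:
                            nxt.append(path + [v])
            frontier = nxt
        return paths

    B = np.zeros(n)
    for t_, u_ in itertools.permutations(range(n), 2):
        paths = all_shortest_paths(t_, u_)
        if not paths:
            continue
        for j in range(n):
            if j in (t_, u_):
                continue
            through = sum(1 for p in paths if j in p[1:-1])
            B[j] += through / len(paths)
    return B / ((n - 1) * (n - 2))


class TestAdjacencyFromCoefficients:
    def test_symmetrized_average_of_absolute_values(self):
        B = np.array([[0.0, 2.0], [-4.0, 0.0]])
        g = adjacency_from_coefficients(B)
        assert g.weights[0, 1] == g.weights[1, 0] == 3.0

    def test_zero_matrix_gives_empty_graph(self):
        g = adjacency_from_coefficients(np.zeros((4, 4)))
        assert np.all(g.weights == 0) and np.all(g.degrees == 0)

    def test_matches_elementwise_formula_on_random_matrix(self, rng):
        B = rng.standard_normal((5, 5))
        g = adjacency_from_coefficients(B)
        for k in range(5):
            for j in range(5):
                expect = 0.0 if k == j else 0.5 * (abs(B[k, j]) + abs(B[j, k]))
                assert g.weights[k, j] == pytest.approx(expect)

    def test_non_square_input_rejected(self):
        with pytest.raises(ValueError, match="square"):
            adjacency_from_coefficients(np.zeros((3, 4)))


class TestAdjacencyFromCorrelation:
    def test_duplicated_column_has_unit_weight(self, rng):
        x = rng.standard_normal(30)
        X = np.column_stack([x, x, rng.standard_normal(30)])
        g = adjacency_from_correlation(X)
        assert g.weights[0, 1] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self, rng):
        X = rng.standard_normal((20000, 2))
        g = adjacency_from_correlation(X)
        assert g.weights[0, 1] < 0.05

    def test_matches_absolute_pearson_on_toy_matrix(self, rng):
        X = rng.standard_normal((12, 4))
        g = adjacency_from_correlation(X)
        for k in range(4):
            for j in range(k + 1, 4):
                r = np.corrcoef(X[:, k], X[:, j])[0, 1]
                assert g.weights[k, j] == pytest.approx(abs(r))

    def test_constant_column_rejected(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="constant"):
            adjacency_from_correlation(X)


class TestNormalizedLaplacian:
    def test_two_gene_graph(self):
        g = WeightedGraph(("a", "b"), np.array([[0.0, 3.0], [3.0, 0.0]]))
        L = normalized_laplacian(g).matrix
        assert np.allclose(L, [[1.0, -1.0], [-1.0, 1.0]])

    def test_isolated_gene_row_and_column_are_zero(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 2.0
        L = normalized_laplacian(WeightedGraph(("a", "b", "c"), W)).matrix
        assert np.all(L[2] == 0) and np.all(L[:, 2] == 0)
        assert L[0, 0] == 1.0

    def test_spectrum_and_null_vector_on_random_graph(self, rng):
        W = np.abs(rng.standard_normal((6, 6)))
        W = 0.5 * (W + W.T)
        np.fill_diagonal(W, 0)
        g = WeightedGraph(tuple("abcdef"), W)
        L = normalized_laplacian(g).matrix
        evals = np.linalg.eigvalsh(L)
        assert evals.min() >= -1e-8 and evals.max() <= 2 + 1e-8
        v = np.sqrt(g.degrees)
        assert np.linalg.norm(L @ v) == pytest.approx(0.0, abs=1e-10)

    def test_spectrum_bound_over_random_coefficient_graphs(self, rng):
        for _ in range(100):
            n = rng.integers(2, 8)
            g = adjacency_from_coefficients(rng.standard_normal((n, n)))
            evals = np.linalg.eigvalsh(normalized_laplacian(g).matrix)
            assert evals.min() >= -1e-8 and evals.max() <= 2 + 1e-8


class TestCentralities:
    def test_star_hubness(self):
        A = np.zeros((11, 11))
        A[0, 1:] = A[1:, 0] = 1.0
        H = hubness(A, p_star=11)
        assert H[0] == pytest.approx(1.0)
        assert np.allclose(H[1:], 0.1)

    def test_hubness_of_fully_connected_gene_is_one(self):
        A = 1.0 - np.eye(5)
        assert hubness(A)[2] == pytest.approx(1.0)

    def test_hubness_matches_degree_count_on_er_graph(self, rng):
        A = (rng.random((9, 9)) < 0.4).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        H = hubness(A)
        assert np.allclose(H, A.sum(axis=0) / 8)

    def test_hubness_universe_too_small(self):
        with pytest.raises(ValueError):
            hubness(np.zeros((1, 1)), p_star=1)

    def test_path_graph_betweenness(self):
        A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        assert np.allclose(betweenness(A), [0.0, 1.0, 0.0])

    def test_complete_graph_betweenness_is_zero(self):
        A = 1.0 - np.eye(4)
        assert np.allclose(betweenness(A), 0.0)

    def test_fewer_than_three_nodes_gives_zeros(self):
        assert np.allclose(betweenness(np.array([[0.0, 1.0], [1.0, 0.0]])), 0.0)

    @pytest.mark.parametrize("n_nodes", [3, 4, 5, 6, 7])
    def test_betweenness_matches_exhaustive_enumeration(self, n_nodes, rng):
        for _ in range(8):
            A = (rng.random((n_nodes, n_nodes)) < 0.45).astype(float)
            A = np.triu(A, 1)
            A = A + A.T
            assert np.allclose(betweenness(A), brute_force_betweenness(A), atol=1e-12)

    def test_centralities_in_unit_interval(self, rng):
        A = (rng.random((8, 8)) < 0.5).astype(float)
        A = np.triu(A, 1) + np.triu(A, 1).T
        H, B = hubness(A), betweenness(A)
        assert np.all((0 <= H) & (H <= 1)) and np.all((0 <= B) & (B <= 1))


class TestBinarize:
    def test_zero_threshold_keeps_positive_weights(self, rng):
        W = np.abs(rng.standard_normal((5, 5))) + 0.1
        W = 0.5 * (W + W.T)
        np.fill_diagonal(W, 0)
        A = binarize(WeightedGraph(tuple("abcde"), W), 0.0)
        assert np.all(A[~np.eye(5, dtype=bool)] == 1)

    def test_threshold_above_max_gives_empty_adjacency(self, rng):
        W = np.abs(rng.standard_normal((4, 4)))
        W = 0.5 * (W + W.T)
        np.fill_diagonal(W, 0)
        A = binarize(W, W.max() + 1)
        assert np.all(A == 0)

    def test_matches_elementwise_comparison(self, rng):
        W = np.abs(rng.standard_normal((6, 6)))
        W = 0.5 * (W + W.T)
        np.fill_diagonal(W, 0)
        thr = float(np.median(W))
        A = binarize(W, thr)
        off = ~np.eye(6, dtype=bool)
        assert np.array_equal(A[off], (W[off] > thr).astype(float))

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((2, 2)), -0.5)


class TestEquivariance:
    def test_permuting_genes_permutes_all_derived_quantities(self, rng):
        n = 7
        W = np.abs(rng.standard_normal((n, n)))
        W = 0.5 * (W + W.T)
        W[W < 0.8] = 0.0
        np.fill_diagonal(W, 0)
        ids = tuple(f"g{i}" for i in range(n))
        g = WeightedGraph(ids, W)
        perm = rng.permutation(n)
        g_p = WeightedGraph(
            tuple(ids[i] for i in perm), W[np.ix_(perm, perm)]
        )
        cs, cs_p = centrality_scores(g), centrality_scores(g_p)
        assert np.allclose(cs.hubness[perm], cs_p.hubness)
        assert np.allclose(cs.betweenness[perm], cs_p.betweenness)
        L = normalized_laplacian(g).matrix
        L_p = normalized_laplacian(g_p).matrix
        assert np.allclose(L[np.ix_(perm, perm)], L_p)


class TestWeightedGraphInvariants:
    def test_asymmetric_weights_rejected(self):
        W = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            WeightedGraph(("a", "b"), W)

    def test_negative_weights_rejected(self):
        W = np.array([[0.0, -1.0], [-1.0, 0.0]])
        with pytest.raises(ValueError, match="nonnegative"):
            WeightedGraph(("a", "b"), W)

    def test_degrees_are_row_sums(self, rng):
        W = np.abs(rng.standard_normal((5, 5)))
        W = 0.5 * (W + W.T)
        np.fill_diagonal(W, 0)
        g = WeightedGraph(tuple("abcde"), W)
        assert np.allclose(g.degrees, g.weights.sum(axis=1))
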