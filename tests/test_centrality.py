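import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from erdosnet import centrality as ct
from erdosnet.gens import compute_gens, importance
from erdosnet.graph import ParameterError, WeightedGraph, generate_ba, generate_er, largest_component
from erdosnet.proximity import mfpt_matrix

TIGHT = dict(tol=1e-10, max_sweeps=200_000)


@pytest.fixture
def star_psi(star4):
    return importance(compute_gens(star4, **TIGHT))


class TestErdosCentrality:
    def test_star_values(self, star4, star_psi):
        psi_sum = ct.erdos_centrality(star_psi, star4)
        assert np.allclose(psi_sum, [3.0, 0.5, 0.5, 0.5], atol=1e-7)

    def test_single_edge_symmetric(self):
        g = WeightedGraph(2, [(0, 1, 1.0)])
        psi = importance(compute_gens(g))
        assert np.allclose(ct.erdos_centrality(psi, g), [1.0, 1.0])

    def test_correlates_with_degree_on_ba(self):
        from scipy.stats import spearmanr
        g = generate_ba(512, 10, seed=4)
        psi = importance(compute_gens(g))
        rho = spearmanr(ct.erdos_centrality(psi, g), g.degrees).statistic
        assert rho > 0.9


class TestImportanceWalk:
    def test_star_transition_rows(self, star_psi):
        P = ct.importance_transition(star_psi)
        assert np.allclose(P[1], [0.6, 0.0, 0.2, 0.2], atol=1e-7)
        assert np.allclose(P[0], [0.0, 1 / 3, 1 / 3, 1 / 3], atol=1e-7)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(np.diag(P) == 0)

    def test_two_node_walk_is_deterministic(self, two_node):
        P = ct.importance_transition(importance(compute_gens(two_node)))
        assert np.allclose(P, [[0, 1], [1, 0]])

    def test_star_teleport_probabilities(self, star4, star_psi):
        # leaf: 1 - (sum_l psi_l,leaf)^-1 = 1 - (5/3)^-1 = 0.4
        p_leaf = ct.teleport_probability(star_psi, star4, 1)
        assert np.isclose(p_leaf, 0.4, atol=1e-7)
        closed = 1.0 - 1.0 / star_psi[:, 1].sum()
        assert np.isclose(p_leaf, closed, atol=1e-10)
        assert ct.teleport_probability(star_psi, star4, 0) == 0.0

    def test_two_node_teleport_is_zero(self, two_node):
        psi = importance(compute_gens(two_node))
        assert ct.teleport_probability(psi, two_node, 0) == 0.0

    def test_star_stationary_distribution(self, star_psi):
        pi = ct.leading_eigenvector(ct.importance_transition(star_psi))
        assert np.allclose(pi, [0.375, 5 / 24, 5 / 24, 5 / 24], atol=1e-7)

    def test_doubly_stochastic_gives_uniform(self):
        # cycle walk: P doubly stochastic => uniform stationary distribution
        n = 6
        P = np.zeros((n, n))
        for i in range(n):
            P[i, (i - 1) % n] = P[i, (i + 1) % n] = 0.5
        assert np.allclose(ct.leading_eigenvector(P), 1 / n, atol=1e-10)

    def test_non_stochastic_rejected(self):
        with pytest.raises(ValueError):
            ct.leading_eigenvector(np.array([[0.5, 0.2], [0.3, 0.7]]))


class TestPageRank:
    def test_gamma_zero_is_uniform(self, star4):
        assert np.allclose(ct.pagerank(star4, 0.0), 0.25)

    def test_gamma_one_is_degree_proportional(self, star4):
        assert np.allclose(ct.pagerank(star4, 1.0), [0.5, 1 / 6, 1 / 6, 1 / 6])

    def test_matches_damped_power_iteration_oracle(self, star4):
        gamma = 0.85
        n = star4.n
        a = star4.adjacency.toarray()
        M = a / star4.degrees[np.newaxis, :]
        x = np.full(n, 1.0 / n)
        for _ in range(10_000):
            x = (1 - gamma) / n + gamma * (M @ x)
        assert np.allclose(ct.pagerank(star4, gamma), x / x.sum(), atol=1e-10)

    def test_continuity_in_gamma(self):
        g, _ = largest_component(generate_er(64, 4, seed=8))
        d = ct.pagerank(g, 0.85) - ct.pagerank(g, 0.85 + 1e-6)
        assert np.max(np.abs(d)) < 1e-4

    def test_invalid_gamma(self, star4):
        with pytest.raises(ParameterError):
            ct.pagerank(star4, 1.5)


class TestClassicalCentralities:
    def test_degree_and_betweenness_hand_values(self, star4, path3):
        assert np.array_equal(ct.degree_centrality(star4), [3, 1, 1, 1])
        # star: every leaf pair's shortest path passes the centre
        assert np.allclose(ct.betweenness_centrality(star4), [1.0, 0, 0, 0])
        # path 0-1-2: the middle node covers the single non-adjacent pair
        assert np.allclose(ct.betweenness_centrality(path3), [0.0, 1.0, 0.0])


class TestRandomWalkCentrality:
    def test_star_potential_difference(self, star4):
        c = ct.random_walk_centrality(mfpt_matrix(star4))
        assert np.isclose(abs(c[0] - c[1]), 4.0, atol=1e-9)
        assert c[0] > c[1]  # hub is easiest to reach => most central

    def test_cycle_is_uniform(self):
        g = WeightedGraph(6, [(i, (i + 1) % 6, 1.0) for i in range(6)])
        c = ct.random_walk_centrality(mfpt_matrix(g))
        assert np.allclose(c, 0.0, atol=1e-9)

    def test_potential_identity_on_er(self):
        g, _ = largest_component(generate_er(32, 4, seed=3))
        tau = mfpt_matrix(g)
        c = ct.random_walk_centrality(tau)  # raises if residual > 1e-8
        resid = np.abs((tau - tau.T) - (c[:, None] - c[None, :]))
        assert np.max(resid) < 1e-8


class TestNonBacktracking:
    def test_symmetric_graphs_are_uniform(self):
        k4 = WeightedGraph(4, [(i, j, 1.0) for i in range(4) for j in range(i + 1, 4)])
        c6 = WeightedGraph(6, [(i, (i + 1) % 6, 1.0) for i in range(6)])
        assert np.allclose(ct.nonbacktracking_centrality(k4), 0.25, atol=1e-9)
        assert np.allclose(ct.nonbacktracking_centrality(c6), 1 / 6, atol=1e-9)

    def test_tree_rejected(self, star4):
        with pytest.raises(ValueError):
            ct.nonbacktracking_centrality(star4)

    def test_matches_dense_power_iteration_oracle(self):
        from erdosnet.centrality import _hashimoto

        g, _ = largest_component(generate_er(64, 6, seed=6))
        B, heads = _hashimoto(g)
        Bd = B.toarray()
        y = np.full(Bd.shape[0], 1.0)
        for _ in range(5000):
            y_new = Bd @ y  # brute-force power iteration on the edge matrix
            y_new /= np.linalg.norm(y_new)
            if np.max(np.abs(y_new - y)) < 1e-14:
                y = y_new
                break
            y = y_new
        oracle = np.bincount(heads, weights=np.abs(y), minlength=g.n)
        oracle = oracle / oracle.sum()
        assert np.allclose(ct.nonbacktracking_centrality(g), oracle, atol=1e-8)


class TestRankIntersection:
    def test_identical_lists_give_one(self):
        o = np.array([3, 1, 0, 2])
        for n in range(1, 5):
            assert ct.top_n_intersection(o, o, n) == 1.0

    def test_worked_example(self):
        oX = np.array([0, 1, 2])
        oY = np.array([0, 2, 1])
        assert np.isclose(ct.top_n_intersection(oX, oY, 2), 0.75)
        assert np.isclose(ct.top_n_intersection(oX, oY, 3), 5 / 6)

    def test_disjoint_top_halves(self):
        oX = np.array([0, 1, 2, 3])
        oY = np.array([2, 3, 0, 1])
        assert ct.top_n_intersection(oX, oY, 2) == 0.0

    def test_out_of_range_n(self):
        o = np.array([0, 1])
        with pytest.raises(ParameterError):
            ct.top_n_intersection(o, o, 3)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.permutations(list(range(12))), st.permutations(list(range(12))))
    def test_symmetry_and_range(self, px, py):
        oX, oY = np.array(px), np.array(py)
        cx = ct.lambda_curve(oX, oY)
        cy = ct.lambda_curve(oY, oX)
        assert np.allclose(cx, cy, atol=1e-12)
        assert np.all((cx >= 0) & (cx <= 1 + 1e-12))

    def test_rank_nodes_tie_break_ascending_id(self):
        scores = np.array([1.0, 2.0, 2.0, 0.5])
        assert np.array_equal(ct.rank_nodes(scores), [1, 2, 0, 3])
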