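"""Nodal graph metrics against hand-derived values, brute force, and networkx."""

import numpy as np
import pytest

from strokeconn.graph import (
    DEFAULT_TAU_GRID,
    ThresholdSweepResult,
    auc,
    betweenness_centrality_node,
    betweenness_centrality_nodes,
    binarize,
    clustering_coefficient_node,
    clustering_coefficient_nodes,
    global_efficiency_node,
    global_efficiency_nodes,
    metric_threshold_sweep,
    shortest_path_lengths,
)

from conftest import random_adjacency


def adj(n, edges):
    A = np.zeros((n, n), dtype=int)
    for i, j in edges:
        A[i, j] = A[j, i] = 1
    return A


PATH3 = adj(3, [(0, 1), (1, 2)])
PATH4 = adj(4, [(0, 1), (1, 2), (2, 3)])
TRIANGLE_PENDANT = adj(4, [(0, 1), (1, 2), (0, 2), (0, 3)])  # triangle 0-1-2, pendant 3 on 0
STAR4 = adj(4, [(0, 1), (0, 2), (0, 3)])
K4 = adj(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])
TWO_COMPONENTS = adj(4, [(0, 1), (2, 3)])


class TestShortestPaths:
    def test_path_graph_hop_counts(self):
        D = shortest_path_lengths(PATH3)
        assert D[0, 2] == 2 and D[0, 1] == 1 and D[0, 0] == 0

    def test_complete_graph_all_distance_one(self):
        D = shortest_path_lengths(K4)
        off = D[~np.eye(4, dtype=bool)]
        assert np.all(off == 1)

    def test_disconnected_pairs_infinite(self):
        D = shortest_path_lengths(TWO_COMPONENTS)
        assert np.isinf(D[0, 2]) and np.isinf(D[1, 3])
        assert np.all(D == D.T)


class TestHandDerivedMetrics:
    @pytest.mark.parametrize(
        "A,node,expected",
        [
            (K4, 0, 1.0),                # complete graph: all paths length 1
            (PATH3, 0, 0.75),            # (1 + 1/2) / 2
            (adj(3, [(0, 1)]), 2, 0.0),  # isolated node
        ],
    )
    def test_global_efficiency(self, A, node, expected):
        assert global_efficiency_node(A, node) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "A,node,expected",
        [
            (adj(3, [(0, 1), (1, 2), (0, 2)]), 0, 1.0),  # triangle node
            (TRIANGLE_PENDANT, 0, 1 / 3),  # one edge of three among {1,2,3}
            (STAR4, 0, 0.0),               # star center: no neighbour edges
        ],
    )
    def test_clustering_coefficient(self, A, node, expected):
        assert clustering_coefficient_node(A, node) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "A,node,expected",
        [
            (PATH4, 1, 2 / 3),  # pairs (0,2),(0,3) of 3 pairs pass node 1
            (K4, 0, 0.0),
            (STAR4, 0, 1.0),    # all leaf pairs route through the center
        ],
    )
    def test_betweenness_centrality(self, A, node, expected):
        assert betweenness_centrality_node(A, node) == pytest.approx(expected)


def brute_force_betweenness(A: np.ndarray) -> np.ndarray:
    """Enumerate all shortest paths by DFS over a BFS-layered DAG."""
    n = A.shape[0]
    D = shortest_path_lengths(A)
    counts = np.zeros(n)

    def all_shortest_paths(s, t):
        paths = []

        def extend(path):
            v = path[-1]
            if v == t:
                paths.append(list(path))
                return
            for w in np.flatnonzero(A[v]):
                if D[s, w] == D[s, v] + 1 and D[w, t] == D[v, t] - 1:
                    extend(path + [w])

        extend([s])
        return paths

    for s in range(n):
        for t in range(s + 1, n):
            if np.isinf(D[s, t]):
                continue
            paths = all_shortest_paths(s, t)
            for v in range(n):
                if v in (s, t):
                    continue
                through = sum(v in p for p in paths)
                counts[v] += through / len(paths)
    return counts / ((n - 1) * (n - 2) / 2)


def test_betweenness_matches_brute_force_enumeration():
    rng = np.random.default_rng(7)
    for _ in range(100):
        n = int(rng.integers(3, 8))
        A = random_adjacency(rng, n, rng.uniform(0.2, 0.9))
        np.testing.assert_allclose(
            betweenness_centrality_nodes(A), brute_force_betweenness(A), atol=1e-12
        )


def test_metrics_match_networkx_reference():
    nx = pytest.importorskip("networkx")
    rng = np.random.default_rng(11)
    for _ in range(300):
        n = int(rng.integers(3, 8))
        A = random_adjacency(rng, n, rng.uniform(0.1, 0.95))
        G = nx.from_numpy_array(A)
        spl = dict(nx.all_pairs_shortest_path_length(G))
        ge_ref = np.array(
            [sum(1 / d for t, d in spl[s].items() if t != s) / (n - 1) for s in range(n)]
        )
        cc_ref = np.array([nx.clustering(G, v) for v in range(n)])
        bc_ref_map = nx.betweenness_centrality(G, normalized=True)
        bc_ref = np.array([bc_ref_map[v] for v in range(n)])
        np.testing.assert_allclose(global_efficiency_nodes(A), ge_ref, atol=1e-12)
        np.testing.assert_allclose(clustering_coefficient_nodes(A), cc_ref, atol=1e-12)
        np.testing.assert_allclose(betweenness_centrality_nodes(A), bc_ref, atol=1e-12)


class TestBinarize:
    def test_strictly_above_threshold(self):
        W = np.array([[1.0, 0.2, 0.1], [0.2, 1.0, 0.15], [0.1, 0.15, 1.0]])
        g = binarize(W, 0.15)
        assert g.A[0, 1] == 1 and g.A[0, 2] == 0 and g.A[1, 2] == 0

    def test_low_threshold_gives_complete_graph(self):
        W = np.full((4, 4), 0.5)
        np.fill_diagonal(W, 1.0)
        g = binarize(W, -0.99)
        assert g.A.sum() == 12

    def test_threshold_at_max_weight_gives_empty_graph(self):
        W = np.full((4, 4), 0.5)
        np.fill_diagonal(W, 1.0)
        assert binarize(W, 0.5).A.sum() == 0

    def test_negative_weights_never_create_edges(self):
        W = np.array([[1.0, -0.9], [-0.9, 1.0]])
        assert binarize(W, 0.15).A.sum() == 0


class TestSweepAndAuc:
    def test_complete_weights_give_unit_ge_curve(self):
        W = np.full((5, 5), 0.9)
        np.fill_diagonal(W, 1.0)
        sweep = metric_threshold_sweep(W)
        assert np.allclose(sweep.values["GE"], 1.0)

    def test_subthreshold_weights_give_zero_curves(self):
        W = np.full((5, 5), 0.1)
        np.fill_diagonal(W, 1.0)
        sweep = metric_threshold_sweep(W)
        for m in ("GE", "CC", "BC"):
            assert np.allclose(sweep.values[m], 0.0)

    def test_step_change_where_grid_straddles_weight(self):
        W = np.full((4, 4), 0.3)
        np.fill_diagonal(W, 1.0)
        sweep = metric_threshold_sweep(W, grid=np.array([0.25, 0.3, 0.35]))
        ge = sweep.values["GE"]
        assert np.allclose(ge[0], 1.0)       # 0.3 > 0.25: complete
        assert np.allclose(ge[1:], 0.0)      # strict: 0.3 > 0.3 is false

    def test_constant_curve_auc_is_rectangle(self):
        grid = DEFAULT_TAU_GRID
        sweep = ThresholdSweepResult(grid, {"GE": np.ones((grid.size, 2))})
        np.testing.assert_allclose(auc(sweep).auc["GE"], 0.35)

    def test_linear_curve_auc_closed_form(self):
        grid = DEFAULT_TAU_GRID
        line = np.linspace(0, 1, grid.size)[:, None]
        sweep = ThresholdSweepResult(grid, {"GE": line})
        np.testing.assert_allclose(auc(sweep).auc["GE"], 0.175)

    def test_auc_is_linear_in_the_curves(self):
        rng = np.random.default_rng(3)
        grid = DEFAULT_TAU_GRID
        c1 = rng.random((grid.size, 4))
        c2 = rng.random((grid.size, 4))
        a, b = 2.5, -1.25
        lhs = auc(ThresholdSweepResult(grid, {"GE": a * c1 + b * c2})).auc["GE"]
        rhs = (
            a * auc(ThresholdSweepResult(grid, {"GE": c1})).auc["GE"]
            + b * auc(ThresholdSweepResult(grid, {"GE": c2})).auc["GE"]
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)


def test_raising_threshold_never_adds_edges_or_efficiency():
    rng = np.random.default_rng(19)
    for _ in range(20):
        n = 10
        M = rng.uniform(-0.5, 0.9, (n, n))
        W = (M + M.T) / 2
        np.fill_diagonal(W, 1.0)
        prev_deg = None
        prev_ge = None
        for tau in DEFAULT_TAU_GRID[::5]:
            A = binarize(W, tau).A
            deg = A.sum(axis=1)
            ge = global_efficiency_nodes(A)
            if prev_deg is not None:
                assert np.all(deg <= prev_deg)
                assert np.all(ge <= prev_ge + 1e-12)
            prev_deg, prev_ge = deg, ge
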