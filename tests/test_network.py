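"""Spearman edges, graph metrics and the current-flow betweenness."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bipolarnet.network import (
    NetworkError,
    SymptomNetwork,
    build_network,
    current_flow_betweenness,
    export_network,
    network_density,
    node_strength,
    prune_edges,
    random_walk_betweenness,
    read_network,
    spearman_edge,
    spearman_matrix,
    SpearmanNetwork,
)


def random_net(k=6, seed=0, n_patients=20):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_patients, k))
    return build_network(pd.DataFrame(X, columns=[f"i{j}" for j in range(k)]))


def mc_current_flow(A, n_walks=40_000, seed=0):
    """Monte-Carlo absorbing-random-walk oracle for current-flow betweenness.

    For each source-target pair, random walks move with probability
    proportional to conductance until absorbed at the target; the expected
    *net* number of crossings of each edge estimates the electrical
    current, and a node's throughflow is half the sum of absolute expected
    net crossings of its incident edges. Normalised like the implementation.
    """
    A = np.abs(np.asarray(A, float))
    n = A.shape[0]
    rng = np.random.default_rng(seed)
    P = A / A.sum(axis=1, keepdims=True)
    total = np.zeros(n)
    pairs = [(s, t) for s in range(n) for t in range(s + 1, n)]
    for s, t in pairs:
        net_cross = np.zeros((n, n))
        pos = np.full(n_walks, s)
        active = pos != t
        while active.any():
            cur = pos[active]
            u = rng.random(cur.size)
            nxt = (P[cur].cumsum(axis=1) < u[:, None]).sum(axis=1)
            np.add.at(net_cross, (cur, nxt), 1)
            np.add.at(net_cross, (nxt, cur), -1)
            pos[active] = nxt
            active = pos != t
        avg = np.abs(net_cross - net_cross.T) / 2 / n_walks
        through = 0.5 * (avg * (A > 0)).sum(axis=1)
        through[[s, t]] = 0.0
        total += through
    return total / ((n - 1) * (n - 2) / 2)


class TestSpearmanEdge:
    def test_monotone_identity(self):
        assert spearman_edge([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)

    def test_reversal(self):
        assert spearman_edge([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_with_average_ranks(self):
        x, y = [1, 2, 2, 4], [1, 3, 2, 4]
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman_edge(x, y) == pytest.approx(expected)

    def test_constant_vector_is_undefined(self):
        with pytest.raises(NetworkError, match="constant"):
            spearman_edge([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_few_complete_pairs(self):
        with pytest.raises(NetworkError, match="pairwise-complete"):
            spearman_edge([1, 2, np.nan, np.nan], [1, np.nan, 2, 3])

    def test_pairwise_complete_drops_nan(self):
        rho = spearman_edge([1, 2, 3, 4, np.nan], [1, 2, 3, np.nan, 4])
        assert rho == pytest.approx(1.0)

    @pytest.mark.parametrize("transform", [np.exp, lambda v: v ** 3,
                                           lambda v: 2 * v + 7])
    def test_invariant_under_monotone_transforms(self, transform):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=50), rng.normal(size=50)
        assert spearman_edge(transform(x), y) == pytest.approx(
            spearman_edge(x, y))


class TestBuildNetwork:
    def test_identical_rank_orders_give_unit_edges(self):
        X = np.array([[1, 10, 3], [2, 20, 5], [3, 30, 9], [4, 40, 11.0]])
        net = build_network(X)
        iu = np.triu_indices(3, 1)
        np.testing.assert_allclose(net.weights[iu], 1.0)

    def test_independent_items_edge_near_zero(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 4, size=(5000, 2)).astype(float)
        net = build_network(X)
        assert abs(net.weights[0, 1]) < 0.05

    def test_matrix_matches_per_pair_edges(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 4, size=(5, 3)).astype(float)
        X[0, 0] += 0.5  # avoid accidental constant columns
        net = build_network(X)
        for i in range(3):
            for j in range(i + 1, 3):
                assert net.weights[i, j] == pytest.approx(
                    spearman_edge(X[:, i], X[:, j]))

    def test_symmetry_and_validation(self):
        net = random_net()
        assert np.allclose(net.weights, net.weights.T)
        with pytest.raises(NetworkError, match="symmetric"):
            SymptomNetwork(("a", "b"), np.array([[0, 1], [0.5, 0]]), 3)

    def test_group_too_small(self):
        with pytest.raises(NetworkError, match="< 3"):
            build_network(np.ones((2, 4)))


class TestDensityAndStrength:
    def test_density_equals_mean_of_upper_triangle(self):
        net = random_net(k=14)
        iu = np.triu_indices(14, 1)
        assert network_density(net) * 91 == pytest.approx(
            net.weights[iu].sum(), abs=1e-12)

    def test_three_node_example(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.1
        w[0, 2] = w[2, 0] = 0.2
        w[1, 2] = w[2, 1] = 0.3
        net = SymptomNetwork(("a", "b", "c"), w, 5)
        assert network_density(net) == pytest.approx(0.2)
        assert network_density(net, absolute=True) == pytest.approx(0.2)

    def test_star_centre_strength(self):
        k, w = 14, 0.3
        m = np.zeros((k, k))
        m[0, 1:] = m[1:, 0] = w
        net = SymptomNetwork(tuple(f"i{j}" for j in range(k)), m, 5)
        assert node_strength(net, "i0") == pytest.approx(13 * w)
        assert node_strength(net, "i1") == pytest.approx(w)

    def test_strengths_match_row_sums_and_density_identity(self):
        net = random_net(k=4, seed=5)
        s = node_strength(net)
        np.testing.assert_allclose(s.to_numpy(), net.weights.sum(axis=1))
        iu = np.triu_indices(4, 1)
        assert s.sum() == pytest.approx(2 * net.weights[iu].sum())

    def test_unknown_item_raises(self):
        with pytest.raises(NetworkError, match="unknown"):
            node_strength(random_net(), "nope")


class TestRandomWalkBetweenness:
    def test_path_closed_form(self):
        w = np.array([[0, 0.4, 0], [0.4, 0, 0.4], [0, 0.4, 0]])
        net = SymptomNetwork(("a", "b", "c"), w, 5)
        assert random_walk_betweenness(net, "b") == pytest.approx(1.0)
        assert random_walk_betweenness(net, "a") == pytest.approx(0.0, abs=1e-12)

    def test_four_cycle_symmetry(self):
        A = nx.to_numpy_array(nx.cycle_graph(4)) * 0.5
        b = current_flow_betweenness(A)
        np.testing.assert_allclose(b, b[0])

    def test_invariant_under_conductance_scaling(self):
        net = random_net(k=6, seed=7)
        b1 = current_flow_betweenness(net.weights)
        b2 = current_flow_betweenness(net.weights * 0.2)
        np.testing.assert_allclose(b1, b2, atol=1e-12)

    def test_matches_networkx_current_flow(self):
        for seed in (0, 1, 2):
            net = random_net(k=7, seed=seed)
            A = np.abs(net.weights)
            G = nx.from_numpy_array(A)
            expected = nx.current_flow_betweenness_centrality(
                G, weight="weight", normalized=True)
            np.testing.assert_allclose(
                current_flow_betweenness(net.weights),
                [expected[i] for i in range(7)], atol=1e-10)

    def test_matches_monte_carlo_walk_oracle(self):
        net = random_net(k=5, seed=11)
        mc = mc_current_flow(net.weights, n_walks=30_000, seed=4)
        np.testing.assert_allclose(
            current_flow_betweenness(net.weights), mc, atol=0.03)

    def test_disconnected_graph_names_components(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.5
        w[2, 3] = w[3, 2] = 0.5
        with pytest.raises(NetworkError, match="components"):
            current_flow_betweenness(w)

    def test_permutation_invariance_of_all_metrics(self):
        net = random_net(k=6, seed=13)
        perm = np.random.default_rng(0).permutation(6)
        permuted = SymptomNetwork(
            tuple(net.items[i] for i in perm),
            net.weights[np.ix_(perm, perm)], net.n_patients)
        assert network_density(permuted) == pytest.approx(network_density(net))
        for metric in (node_strength, random_walk_betweenness):
            a = metric(net).sort_index()
            b = metric(permuted).sort_index()
            np.testing.assert_allclose(a.to_numpy(), b.to_numpy())


class TestPruneAndExport:
    def test_prune_rules(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.19
        w[0, 2] = w[2, 0] = 0.21
        w[1, 2] = w[2, 1] = -0.5
        net = SymptomNetwork(("a", "b", "c"), w, 5)
        pruned = prune_edges(net, 0.2)
        assert pruned.weights[0, 1] == 0.0
        assert pruned.weights[0, 2] == 0.21
        assert pruned.weights[1, 2] == -0.5  # magnitude rule keeps negatives
        assert net.weights[0, 1] == 0.19  # analysis matrix untouched

    @pytest.mark.parametrize("fmt", ["matrix", "edgelist", "graphml"])
    def test_round_trip(self, fmt, tmp_path):
        net = random_net(k=5, seed=21)
        path = tmp_path / f"net.{fmt}"
        export_network(net, fmt, path)
        back = read_network(fmt, path, n_patients=net.n_patients)
        assert back.items == net.items
        np.testing.assert_allclose(back.weights, net.weights, atol=1e-14)

    def test_edge_list_row_count_matches_pruning(self):
        net = random_net(k=6, seed=2)
        pruned = prune_edges(net, 0.2)
        retained = int((np.abs(net.weights[np.triu_indices(6, 1)]) >= 0.2).sum())
        assert len(pruned.edge_list()) == retained


class TestEstimator:
    def test_fitted_attributes_consistent(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.integers(0, 4, size=(30, 5)).astype(float),
                         columns=list("abcde"))
        est = SpearmanNetwork().fit(X)
        assert est.network_.n_patients == 30
        assert est.density_ == pytest.approx(network_density(est.network_))
        np.testing.assert_allclose(
            est.strengths_.to_numpy(),
            node_strength(est.network_).to_numpy())
        assert est.get_params() == {"absolute": False}
        assert est.set_params(absolute=True).absolute is True
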