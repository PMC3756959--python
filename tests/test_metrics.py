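import numpy as np
import pytest

from conftest import random_graph
from oracles import (
    bf_clustering_binary,
    bf_clustering_weighted,
    bf_global_efficiency,
    bf_local_efficiency,
    bf_path_lengths,
    bf_shortest_paths,
)
from swallownet.construction import Network
from swallownet.metrics import (
    EstimationError,
    characteristic_path_length,
    clustering,
    clustering_degree_polyfit,
    degree,
    global_efficiency,
    hierarchy_beta,
    local_efficiency,
    network_summary,
    shortest_paths,
)


def _binary(adj):
    return Network(np.asarray(adj, dtype=float), "binary")


def _path3():
    return _binary([[0, 1, 0], [1, 0, 1], [0, 1, 0]])


def _complete(n):
    adj = np.ones((n, n)) - np.eye(n)
    return _binary(adj)


def _star(n):
    adj = np.zeros((n, n))
    adj[0, 1:] = adj[1:, 0] = 1
    return _binary(adj)


def fan_graph(ks):
    """Disjoint fans: hub + path of k neighbors; every node has C = 2/k exactly."""
    total = sum(k + 1 for k in ks)
    adj = np.zeros((total, total))
    offset = 0
    for k in ks:
        hub = offset
        spokes = list(range(offset + 1, offset + k + 1))
        for s in spokes:
            adj[hub, s] = adj[s, hub] = 1
        for a, b in zip(spokes, spokes[1:]):
            adj[a, b] = adj[b, a] = 1
        offset += k + 1
    return _binary(adj)


class TestDegree:
    def test_edgeless_and_complete(self):
        k, K = degree(_binary(np.zeros((4, 4))))
        assert K == 0 and (k == 0).all()
        k, K = degree(_complete(90))
        assert K == 89.0 and (k == 89).all()

    def test_weighted_strength(self):
        adj = np.array([[0, 0.5, 0.25], [0.5, 0, 0], [0.25, 0, 0]])
        k, K = degree(Network(adj, "weighted"))
        np.testing.assert_allclose(k, [0.75, 0.5, 0.25])
        assert K == pytest.approx(0.5)


class TestClustering:
    def test_complete_graph_fully_clustered(self):
        C, Cp = clustering(_complete(5))
        np.testing.assert_allclose(C, 1.0)
        assert Cp == 1.0

    def test_star_has_no_triangles(self):
        C, Cp = clustering(_star(6))
        np.testing.assert_array_equal(C, 0.0)
        assert Cp == 0.0

    def test_five_node_frozen_example(self):
        # edges 12,13,23,34,45 (1-indexed): C = (1, 1, 1/3, 0, 0), Cp = 7/15
        adj = np.zeros((5, 5))
        for a, b in [(0, 1), (0, 2), (1, 2), (2, 3), (3, 4)]:
            adj[a, b] = adj[b, a] = 1
        C, Cp = clustering(_binary(adj))
        np.testing.assert_allclose(C, [1, 1, 1 / 3, 0, 0])
        assert Cp == pytest.approx(7 / 15)

    def test_weighted_reduces_to_binary_on_unit_weights(self):
        rng = np.random.default_rng(3)
        adj = random_graph(rng, 7, weighted=False)
        Cb, _ = clustering(_binary(adj))
        Cw, _ = clustering(Network(adj, "weighted"))
        np.testing.assert_allclose(Cb, Cw, atol=1e-12)


class TestShortestPaths:
    def test_single_weighted_edge_inverse_length(self):
        adj = np.array([[0, 0.5], [0.5, 0]])
        d = shortest_paths(Network(adj, "weighted"))
        assert d[0, 1] == pytest.approx(2.0)

    def test_binary_path_graph_hops(self):
        d = shortest_paths(_path3())
        assert d[0, 2] == 2.0

    def test_disconnected_pairs_infinite(self):
        adj = np.zeros((3, 3))
        adj[0, 1] = adj[1, 0] = 1
        d = shortest_paths(_binary(adj))
        assert np.isinf(d[0, 2]) and np.isinf(d[2, 1])

    def test_weighted_six_node_matches_enumeration(self):
        rng = np.random.default_rng(11)
        adj = random_graph(rng, 6, weighted=True, p=0.6)
        d = shortest_paths(Network(adj, "weighted"))
        np.testing.assert_allclose(d, bf_shortest_paths(adj, weighted=True), atol=1e-10)


class TestPathLength:
    def test_complete_graph_unit_length_both_kinds(self):
        for kind in ("arithmetic", "harmonic"):
            _, Lp = characteristic_path_length(_complete(5), kind=kind)
            assert Lp == pytest.approx(1.0)

    def test_path_graph_harmonic_value(self):
        # reciprocal distances over 6 ordered pairs: mean = 5/6, Lp = 6/5
        _, Lp = characteristic_path_length(_path3(), kind="harmonic")
        assert Lp == pytest.approx(1.2)

    def test_disconnected_conventions(self):
        net = _binary(np.zeros((2, 2)))
        _, Lp_h = characteristic_path_length(net, kind="harmonic")
        assert np.isinf(Lp_h)  # mean reciprocal distance 0
        adj = np.zeros((3, 3))
        adj[0, 1] = adj[1, 0] = 1
        _, Lp_a = characteristic_path_length(_binary(adj), kind="arithmetic")
        assert np.isinf(Lp_a)  # infinite distances propagate
        _, Lp_h2 = characteristic_path_length(_binary(adj), kind="harmonic")
        assert np.isfinite(Lp_h2)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            characteristic_path_length(_path3(), kind="median")


class TestEfficiency:
    def test_complete_and_empty_limits(self):
        _, e = global_efficiency(_complete(6))
        assert e == pytest.approx(1.0)
        _, e = global_efficiency(_binary(np.zeros((4, 4))))
        assert e == 0.0

    def test_path_graph_frozen_value(self):
        _, e = global_efficiency(_path3())
        assert e == pytest.approx(5 / 6)

    def test_local_efficiency_limits(self):
        _, e = local_efficiency(_complete(5))
        assert e == pytest.approx(1.0)
        per_node, e = local_efficiency(_star(5))
        assert e == 0.0 and (per_node == 0).all()

    def test_local_efficiency_matches_oracle_on_clustered_graph(self):
        adj = np.zeros((5, 5))
        for a, b in [(0, 1), (0, 2), (1, 2), (2, 3), (3, 4)]:
            adj[a, b] = adj[b, a] = 1
        per_node, _ = local_efficiency(_binary(adj))
        np.testing.assert_allclose(per_node, bf_local_efficiency(adj, False), atol=1e-12)


class TestOracleEquivalenceSweep:
    @pytest.mark.parametrize("mode", ["binary", "weighted"])
    def test_thirty_random_graphs(self, mode):
        rng = np.random.default_rng(99)
        for _ in range(30):
            n = int(rng.integers(2, 8))
            adj = random_graph(rng, n, weighted=(mode == "weighted"))
            net = Network(adj, mode)
            weighted = mode == "weighted"
            np.testing.assert_allclose(degree(net)[0], adj.sum(axis=1), atol=1e-12)
            oc = bf_clustering_weighted(adj) if weighted else bf_clustering_binary(adj)
            np.testing.assert_allclose(clustering(net)[0], oc, atol=1e-10)
            d = shortest_paths(net)
            od = bf_shortest_paths(adj, weighted)
            np.testing.assert_allclose(d, od, atol=1e-10)
            np.testing.assert_allclose(
                global_efficiency(net)[0], bf_global_efficiency(adj, weighted)[0], atol=1e-10
            )
            np.testing.assert_allclose(
                local_efficiency(net)[0], bf_local_efficiency(adj, weighted), atol=1e-10
            )


class TestHierarchy:
    def test_planted_inverse_power_law(self):
        fit = hierarchy_beta(fan_graph([4, 6, 8, 10, 12]))
        assert fit.beta == pytest.approx(1.0, abs=1e-6)
        assert fit.intercept == pytest.approx(np.log(2.0), abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_flat_clustering_gives_zero_slope(self):
        # two complete components of different size: C = 1 at k = 2 and k = 3
        adj = np.zeros((7, 7))
        adj[:3, :3] = 1 - np.eye(3)
        adj[3:, 3:] = 1 - np.eye(4)
        fit = hierarchy_beta(_binary(adj))
        assert fit.beta == pytest.approx(0.0, abs=1e-9)

    def test_complete_graph_degenerate(self):
        with pytest.raises(EstimationError):
            hierarchy_beta(_complete(6))

    def test_too_few_eligible_nodes(self):
        with pytest.raises(EstimationError):
            hierarchy_beta(_star(5))

    def test_polynomial_diagnostic_needs_enough_nodes(self):
        net = fan_graph([4, 6, 8, 10, 12])
        coeffs = clustering_degree_polyfit(net, order=2)
        assert coeffs.shape == (3,)
        with pytest.raises(EstimationError):
            clustering_degree_polyfit(fan_graph([4]), order=5)


class TestNetworkSummary:
    def test_summary_consistency_with_parts(self):
        rng = np.random.default_rng(5)
        net = _binary(random_graph(rng, 12, weighted=False, p=0.4))
        s = network_summary(net)
        assert s.K_mean == degree(net)[1]
        assert s.Cp == clustering(net)[1]
        assert s.Eglob == global_efficiency(net)[1]
        _, harm = bf_path_lengths(net.adjacency, weighted=False)
        assert s.Lp == pytest.approx(harm, abs=1e-10)

    def test_empty_network_summary(self):
        s = network_summary(_binary(np.zeros((5, 5))))
        assert s.K_mean == 0 and s.Cp == 0 and s.Eglob == 0
        assert s.beta is None
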