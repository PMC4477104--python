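"""Graph metrics against closed forms and independent brute-force oracles."""

import numpy as np
import networkx as nx
import pytest

from fcgraph import metrics as met
from fcgraph.connectivity import SparsityGrid

from conftest import net_from_weights, ring_lattice
import oracles


class TestClustering:
    def test_complete_graph_is_fully_clustered(self, k4):
        per_node, c_p = met.clustering_coefficient(k4)
        assert np.allclose(per_node, 1.0)
        assert c_p == pytest.approx(1.0)

    def test_star_has_no_triangles(self, star5):
        per_node, c_p = met.clustering_coefficient(star5)
        assert np.allclose(per_node, 0.0)
        assert c_p == 0.0

    def test_weighted_triangle_matches_enumeration(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[0, 2] = w[2, 0] = 0.5
        w[1, 2] = w[2, 1] = 0.5
        w[2, 3] = w[3, 2] = 0.8  # pendant
        net = net_from_weights(w)
        per_node, _ = met.clustering_coefficient(net)
        assert np.allclose(per_node, oracles.oracle_clustering_onnela(w),
                           atol=1e-12)

    def test_binary_weights_reduce_to_watts_strogatz(self, rng):
        w = oracles.random_weighted_graph(10, 0.5, rng)
        w = (w > 0).astype(float)
        net = net_from_weights(w)
        per_node, _ = met.clustering_coefficient(net)
        g = nx.from_numpy_array(w)
        expected = np.array([nx.clustering(g)[i] for i in range(10)])
        assert np.allclose(per_node, expected, atol=1e-12)

    def test_barrat_variant_on_binary_equals_onnela(self, rng):
        w = (oracles.random_weighted_graph(8, 0.5, rng) > 0).astype(float)
        net = net_from_weights(w)
        a, _ = met.clustering_coefficient(net, "onnela")
        b, _ = met.clustering_coefficient(net, "barrat")
        assert np.allclose(a, b, atol=1e-12)


class TestDistancesAndEfficiency:
    def test_path_graph_closed_forms(self, path3):
        d = met.shortest_path_lengths(path3)
        assert d[0, 2] == pytest.approx(2.0)
        assert met.characteristic_path_length(path3) == pytest.approx(4 / 3)
        assert met.global_efficiency(path3) == pytest.approx(5 / 6)

    def test_complete_graph_closed_forms(self, k4):
        assert met.characteristic_path_length(k4) == pytest.approx(1.0)
        assert met.global_efficiency(k4) == pytest.approx(1.0)
        assert met.local_efficiency(k4) == pytest.approx(1.0)
        assert np.allclose(met.nodal_efficiency(k4), 1.0)

    def test_disconnected_pairs_are_infinite(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        net = net_from_weights(w)
        d = met.shortest_path_lengths(net)
        assert np.isinf(d[0, 2]) and np.isinf(d[1, 3])
        # L_p averages reachable pairs only; efficiency treats 1/inf as 0
        assert met.characteristic_path_length(net) == pytest.approx(1.0)
        assert met.global_efficiency(net) == pytest.approx(4 / 12)

    def test_nodal_efficiency_mean_equals_global(self, rng):
        w = oracles.random_weighted_graph(9, 0.4, rng)
        net = net_from_weights(w)
        assert met.nodal_efficiency(net).mean() == \
            pytest.approx(met.global_efficiency(net), abs=1e-12)


class TestBetweenness:
    def test_star_center_carries_all_paths(self, star5):
        b = met.betweenness(star5)
        assert b[0] == pytest.approx(6.0)
        assert np.allclose(b[1:], 0.0)

    def test_cycle_ties_split_fractionally(self):
        w = np.zeros((4, 4))
        for i in range(4):
            j = (i + 1) % 4
            w[i, j] = w[j, i] = 1.0
        b = met.betweenness(net_from_weights(w))
        assert np.allclose(b, 0.5)

    def test_matches_exhaustive_path_enumeration(self, rng):
        for _ in range(10):
            w = oracles.random_weighted_graph(7, 0.45, rng)
            net = net_from_weights(w)
            assert np.allclose(met.betweenness(net),
                               oracles.oracle_betweenness(w), atol=1e-9)


class TestDegree:
    def test_closed_forms(self, k4, star5):
        assert np.array_equal(met.degree(k4), [3, 3, 3, 3])
        assert np.array_equal(met.degree(star5), [4, 1, 1, 1, 1])
        empty = net_from_weights(np.zeros((5, 5)))
        assert np.array_equal(met.degree(empty), np.zeros(5, dtype=int))

    def test_mean_degree_tracks_sparsity(self, rng):
        from fcgraph.connectivity import (ConnectivityMatrix,
                                          threshold_at_sparsity)
        w = rng.uniform(-1, 1, size=(30, 30))
        w = np.triu(w, 1)
        w = w + w.T
        conn = ConnectivityMatrix(w, [f"R{i}" for i in range(30)])
        for s in (0.1, 0.25, 0.4):
            net = threshold_at_sparsity(conn, s)
            assert met.degree(net).mean() == \
                pytest.approx(2 * net.edge_count / 30)
            assert net.edge_count == round(s * 30 * 29 / 2)


class TestRewireNull:
    def test_degree_sequence_preserved(self, rng):
        for trial in range(5):
            w = oracles.random_weighted_graph(20, 0.25, rng)
            net = net_from_weights(w)
            null = met.rewire_null(net, seed=trial)
            assert np.array_equal(met.degree(null), met.degree(net))
            # weight multiset preserved too
            assert np.allclose(
                sorted(v for _, _, v in null.edges()),
                sorted(v for _, _, v in net.edges()))

    def test_complete_graph_is_rigid(self, k4):
        with pytest.warns(RuntimeWarning, match="swaps"):
            null = met.rewire_null(k4, seed=0)
        assert np.allclose(null.weights, k4.weights)

    def test_rewiring_destroys_lattice_clustering(self):
        net = ring_lattice(50, 4)
        _, c_lattice = met.clustering_coefficient(net)
        c_nulls = []
        for i in range(20):
            _, c = met.clustering_coefficient(met.rewire_null(net, seed=i))
            c_nulls.append(c)
        assert np.mean(c_nulls) < c_lattice


class TestSmallWorldIndices:
    def test_ring_lattice_is_small_world_substrate(self):
        net = ring_lattice(50, 4)
        sw = met.small_world_indices(net, n_random=30, seed=0)
        assert sw.gamma > 2.0
        assert sw.lambda_ > 1.0
        assert sw.sigma == pytest.approx(sw.gamma / sw.lambda_)

    def test_randomized_graph_self_normalizes(self, rng):
        # dense substrate so the input's own clustering fluctuation is small
        net = met.rewire_null(ring_lattice(90, 20), seed=3)
        sw = met.small_world_indices(net, n_random=100, seed=1)
        assert sw.sigma == pytest.approx(1.0, abs=0.1)


class TestAuc:
    def test_constant_curve(self):
        grid = SparsityGrid(0.10, 0.34, 0.01).values
        assert met.auc(np.ones(25), grid) == pytest.approx(0.24)
        assert met.auc(np.full(25, 3.5), grid) == pytest.approx(3.5 * 0.24)

    def test_linear_curve_exact(self):
        grid = SparsityGrid(0.10, 0.34, 0.01).values
        assert met.auc(grid, grid) == pytest.approx((0.34**2 - 0.10**2) / 2)

    def test_matches_naive_loop(self, rng):
        grid = SparsityGrid(0.10, 0.34, 0.01).values
        y = rng.standard_normal(25)
        assert met.auc(y, grid) == pytest.approx(
            oracles.oracle_auc(y, grid), abs=1e-12)

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError):
            met.auc(np.ones(5), np.linspace(0, 1, 6))


class TestPermutationEquivariance:
    def test_node_relabeling_permutes_outputs(self, rng):
        w = oracles.random_weighted_graph(8, 0.5, rng)
        perm = rng.permutation(8)
        wp = w[np.ix_(perm, perm)]
        net, netp = net_from_weights(w), net_from_weights(wp)
        assert np.allclose(met.betweenness(netp),
                           met.betweenness(net)[perm], atol=1e-9)
        assert np.allclose(met.nodal_efficiency(netp),
                           met.nodal_efficiency(net)[perm], atol=1e-12)
        assert met.global_efficiency(netp) == \
            pytest.approx(met.global_efficiency(net), abs=1e-12)
        assert met.local_efficiency(netp) == \
            pytest.approx(met.local_efficiency(net), abs=1e-12)
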