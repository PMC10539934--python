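import numpy as np
import pytest

from eegraph.connectivity import ConnectivityMatrix
from eegraph.graph import (
    BinaryGraph,
    binarize_top_n,
    characteristic_path_length,
    clustering_coefficient,
    global_efficiency,
    local_efficiency,
    nodal_efficiencies,
    nodal_efficiency,
    random_references,
    shortest_path_lengths,
    small_world_sigma,
    sparsity_sweep,
)
from eegraph.montage import CHANNELS
from eegraph.spectral import BAND_BY_NAME
from eegraph.synthetic import make_graph_fixture

from conftest import random_adjacency
from _oracles import (
    clustering_oracle,
    floyd_warshall,
    global_eff_oracle,
    local_eff_oracle,
    nodal_eff_oracle,
    path_length_oracle,
)


def _graph_from_adj(adj):
    labels = tuple(str(i) for i in range(adj.shape[0]))
    return BinaryGraph(labels, adj.astype(bool))


def _random_sym_weights(n, seed):
    rng = np.random.default_rng(seed)
    w = rng.random((n, n))
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return w


class TestBinaryGraph:
    def test_rejects_self_loops(self):
        a = np.eye(3, dtype=bool)
        with pytest.raises(ValueError):
            BinaryGraph(("a", "b", "c"), a)

    def test_edge_list_roundtrip(self, tmp_path):
        g = make_graph_fixture("watts_strogatz", 20, {"k": 4, "p": 0.2}, seed=1)
        path = tmp_path / "g.edges"
        g.write_edgelist(path)
        g2 = BinaryGraph.read_edgelist(path)
        assert g2.labels == g.labels
        assert np.array_equal(g2.adjacency, g.adjacency)


class TestBinarizeTopN:
    def test_sparsity_point_one_keeps_17_edges(self):
        w = _random_sym_weights(19, 0)
        g = binarize_top_n(w, 0.1)
        assert g.n_edges == 17  # round(0.1 * 171)

    def test_sparsity_one_complete_graph(self):
        w = _random_sym_weights(19, 1)
        g = binarize_top_n(w, 1.0)
        assert g.n_edges == 171

    def test_keeps_exactly_the_largest_weights(self):
        w = np.zeros((6, 6))
        marked = [(0, 3), (1, 4), (2, 5), (0, 5), (1, 2)]
        for i, j in marked:
            w[i, j] = w[j, i] = 1.0 + 0.1 * i
        n_pairs = 15
        g = binarize_top_n(w, 5 / n_pairs)
        assert set(g.edges()) == {(str(i), str(j)) for i, j in sorted(marked)}

    def test_deterministic_tie_break(self):
        w = np.ones((5, 5))
        np.fill_diagonal(w, 0.0)
        g1 = binarize_top_n(w, 0.3)
        g2 = binarize_top_n(w, 0.3)
        assert np.array_equal(g1.adjacency, g2.adjacency)
        # lexicographically first pairs win: (0,1), (0,2), (0,3)
        assert set(g1.edges()) == {("0", "1"), ("0", "2"), ("0", "3")}

    def test_connectivity_matrix_input_carries_labels(self):
        w = _random_sym_weights(19, 3)
        cm = ConnectivityMatrix(BAND_BY_NAME["theta"], w / w.max() * 0.9, CHANNELS, 50)
        g = binarize_top_n(cm, 0.2)
        assert g.labels == CHANNELS

    @pytest.mark.parametrize("s", [0.0, -0.1, 1.5])
    def test_sparsity_out_of_range(self, s):
        with pytest.raises(ValueError):
            binarize_top_n(_random_sym_weights(5, 0), s)


class TestShortestPaths:
    def test_complete_graph_all_ones(self):
        g = make_graph_fixture("complete", 6)
        d = shortest_path_lengths(g)
        off = ~np.eye(6, dtype=bool)
        assert (d[off] == 1.0).all()
        assert (np.diag(d) == 0.0).all()

    def test_path_graph_end_to_end(self):
        g = make_graph_fixture("path", 4)
        d = shortest_path_lengths(g)
        assert d[0, 3] == 3.0

    def test_disconnected_pairs_infinite(self):
        adj = np.zeros((4, 4), dtype=int)
        adj[0, 1] = adj[1, 0] = 1
        adj[2, 3] = adj[3, 2] = 1
        d = shortest_path_lengths(_graph_from_adj(adj))
        assert np.isinf(d[0, 2]) and np.isinf(d[1, 3])

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_floyd_warshall(self, seed):
        adj = random_adjacency(10, 0.3, seed)
        d = shortest_path_lengths(_graph_from_adj(adj))
        assert np.array_equal(d, floyd_warshall(adj))


class TestEfficiencies:
    def test_complete_graph_unity(self):
        g = make_graph_fixture("complete", 7)
        assert global_efficiency(g) == pytest.approx(1.0)
        assert local_efficiency(g) == pytest.approx(1.0)

    def test_empty_graph_zero(self):
        g = _graph_from_adj(np.zeros((5, 5), dtype=int))
        assert global_efficiency(g) == 0.0

    def test_path4_hand_value(self):
        # inverse distances: 6 ordered pairs each way:
        # d=1 x3 pairs, d=2 x2, d=3 x1 -> sum inv = 2*(3 + 1 + 1/3) = 26/3
        # E = (26/3) / 12 = 13/18
        g = make_graph_fixture("path", 4)
        assert global_efficiency(g) == pytest.approx(13.0 / 18.0, abs=1e-12)

    def test_star_local_efficiency_zero(self):
        g = make_graph_fixture("star", 4)  # hub + 3 leaves
        assert local_efficiency(g) == 0.0

    def test_triangle_local_efficiency_one(self):
        g = make_graph_fixture("complete", 3)
        assert local_efficiency(g) == pytest.approx(1.0)

    def test_nodal_complete_graph(self):
        g = make_graph_fixture("complete", 8)
        assert np.allclose(nodal_efficiencies(g), 1.0)

    def test_nodal_isolated_node(self):
        adj = np.zeros((4, 4), dtype=int)
        adj[0, 1] = adj[1, 0] = 1
        g = _graph_from_adj(adj)
        assert nodal_efficiency(g, 3) == 0.0

    def test_nodal_path4_end_node(self):
        g = make_graph_fixture("path", 4)
        assert nodal_efficiency(g, 0) == pytest.approx(11.0 / 18.0, abs=1e-12)

    def test_nodal_neighbor_subgraph_variant(self):
        g = make_graph_fixture("complete", 5)
        # every neighbor subgraph of K5 is K4 -> efficiency 1
        assert nodal_efficiency(g, 0, neighbor_subgraph=True) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_oracle_equivalence_random_graphs(self, seed):
        adj = random_adjacency(11, 0.25 + 0.05 * seed, seed)
        g = _graph_from_adj(adj)
        assert global_efficiency(g) == pytest.approx(global_eff_oracle(adj), abs=1e-12)
        assert local_efficiency(g) == pytest.approx(local_eff_oracle(adj), abs=1e-12)
        for i in range(11):
            assert nodal_efficiency(g, i) == pytest.approx(
                nodal_eff_oracle(adj, i), abs=1e-12
            )


class TestClusteringAndPathLength:
    def test_triangle(self):
        g = make_graph_fixture("complete", 3)
        _, c = clustering_coefficient(g)
        assert c == pytest.approx(1.0)

    def test_star_zero_clustering(self):
        g = make_graph_fixture("star", 5)
        _, c = clustering_coefficient(g)
        assert c == 0.0

    def test_triangle_plus_pendant(self):
        g = BinaryGraph.from_edges(
            ("a", "b", "c", "d", "e"),
            [("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")],
        )
        c_i, c = clustering_coefficient(g)
        expect_i, expect = clustering_oracle(g.adjacency.astype(int))
        assert np.allclose(c_i, expect_i)
        assert c == pytest.approx(expect, abs=1e-12)

    def test_complete_graph_L_one(self):
        g = make_graph_fixture("complete", 6)
        assert characteristic_path_length(g) == pytest.approx(1.0)

    def test_path4_L(self):
        g = make_graph_fixture("path", 4)
        assert characteristic_path_length(g) == pytest.approx(5.0 / 3.0, abs=1e-12)

    def test_ring4_L(self):
        g = make_graph_fixture("ring_lattice", 4, {"k": 2})
        assert characteristic_path_length(g) == pytest.approx(4.0 / 3.0, abs=1e-12)

    def test_disconnected_modes(self):
        adj = np.zeros((4, 4), dtype=int)
        adj[0, 1] = adj[1, 0] = 1
        adj[2, 3] = adj[3, 2] = 1
        g = _graph_from_adj(adj)
        assert characteristic_path_length(g) == pytest.approx(1.0)
        assert characteristic_path_length(g, disconnected="inf") == np.inf

    def test_fully_disconnected_undefined(self):
        g = _graph_from_adj(np.zeros((3, 3), dtype=int))
        assert np.isnan(characteristic_path_length(g))

    @pytest.mark.parametrize("seed", range(4))
    def test_oracle_equivalence(self, seed):
        adj = random_adjacency(12, 0.3, seed)
        g = _graph_from_adj(adj)
        c_i, c = clustering_coefficient(g)
        oc_i, oc = clustering_oracle(adj)
        assert np.allclose(c_i, oc_i, atol=1e-12)
        assert c == pytest.approx(oc, abs=1e-12)
        assert characteristic_path_length(g) == pytest.approx(
            path_length_oracle(adj), abs=1e-12, nan_ok=True
        )


class TestRandomReferences:
    def test_degree_sequence_preserved(self):
        g = make_graph_fixture("watts_strogatz", 40, {"k": 4, "p": 0.1}, seed=0)
        refs = random_references(g, n_refs=5, seed=1)
        base = sorted(g.degrees())
        for r in refs:
            assert sorted(r.degrees()) == base

    def test_count_and_determinism(self):
        g = make_graph_fixture("watts_strogatz", 30, {"k": 4, "p": 0.1}, seed=0)
        refs_a = random_references(g, n_refs=100, seed=7)
        refs_b = random_references(g, n_refs=100, seed=7)
        assert len(refs_a) == 100
        for ra, rb in zip(refs_a, refs_b):
            assert np.array_equal(ra.adjacency, rb.adjacency)

    def test_star_falls_back_with_warning(self):
        g = make_graph_fixture("star", 8)
        with pytest.warns(UserWarning, match="rewiring impossible"):
            refs = random_references(g, n_refs=2, seed=0)
        for r in refs:
            assert r.n_edges == g.n_edges

    def test_too_few_edges_rejected(self):
        g = BinaryGraph.from_edges(("a", "b", "c"), [("a", "b")])
        with pytest.raises(ValueError):
            random_references(g)


class TestSmallWorldSigma:
    def test_watts_strogatz_exceeds_one(self):
        g = make_graph_fixture("watts_strogatz", 100, {"k": 4, "p": 0.1}, seed=2)
        assert small_world_sigma(g, n_refs=20, seed=0) > 1.0

    def test_erdos_renyi_near_one(self):
        sigmas = []
        for seed in range(8):
            g = make_graph_fixture("erdos_renyi", 100, {"p": 0.08}, seed=seed)
            sigmas.append(small_world_sigma(g, n_refs=20, seed=seed))
        assert 0.8 <= np.mean(sigmas) <= 1.2

    def test_ring_lattice_ratios(self):
        g = make_graph_fixture("ring_lattice", 100, {"k": 4})
        _, c = clustering_coefficient(g)
        assert c == pytest.approx(0.5)  # closed form for k=4 ring lattice
        refs = random_references(g, n_refs=20, seed=0)
        c_r = np.mean([clustering_coefficient(r)[1] for r in refs])
        l_r = np.mean([characteristic_path_length(r) for r in refs])
        assert c / c_r > 3.0
        assert characteristic_path_length(g) / l_r > 3.0

    def test_ws_beats_degree_matched_er(self):
        wins = 0
        trials = 10
        for seed in range(trials):
            ws = make_graph_fixture("watts_strogatz", 60, {"k": 4, "p": 0.1}, seed=seed)
            er = make_graph_fixture("erdos_renyi", 60, {"p": 4 / 59}, seed=seed + 100)
            if er.n_edges < 2:
                continue
            s_ws = small_world_sigma(ws, n_refs=10, seed=seed)
            s_er = small_world_sigma(er, n_refs=10, seed=seed)
            if s_ws > s_er:
                wins += 1
        assert wins >= int(0.95 * trials) - 1


class TestSparsitySweep:
    def test_global_efficiency_monotone(self):
        w = _random_sym_weights(19, 5)
        sw = sparsity_sweep(w, np.arange(0.1, 0.85, 0.05))
        e = sw.values("e_glob")
        assert (np.diff(e) >= -1e-12).all()

    def test_complete_limit(self):
        w = _random_sym_weights(19, 6)
        sw = sparsity_sweep(w, [1.0])
        m = sw.metrics[0]
        assert m.e_glob == pytest.approx(1.0)
        assert m.e_loc == pytest.approx(1.0)
        assert m.clustering == pytest.approx(1.0)
        assert m.path_length == pytest.approx(1.0)

    def test_grid_points_equal_single_calls(self):
        w = _random_sym_weights(19, 7)
        grid = [0.1, 0.2, 0.3]
        sw = sparsity_sweep(w, grid)
        for s, m in zip(grid, sw.metrics):
            g = binarize_top_n(w, s)
            assert m.e_glob == pytest.approx(global_efficiency(g), abs=1e-12)
            assert m.e_loc == pytest.approx(local_efficiency(g), abs=1e-12)

    def test_invalid_grid(self):
        w = _random_sym_weights(10, 8)
        with pytest.raises(ValueError):
            sparsity_sweep(w, [0.3, 0.2])
        with pytest.raises(ValueError):
            sparsity_sweep(w, [0.0, 0.5])

    def test_relabeling_invariance_of_metrics(self):
        rng = np.random.default_rng(9)
        adj = random_adjacency(12, 0.3, 9)
        perm = rng.permutation(12)
        g = _graph_from_adj(adj)
        gp = _graph_from_adj(adj[np.ix_(perm, perm)])
        assert global_efficiency(g) == pytest.approx(global_efficiency(gp), abs=1e-12)
        assert local_efficiency(g) == pytest.approx(local_efficiency(gp), abs=1e-12)
        assert clustering_coefficient(g)[1] == pytest.approx(
            clustering_coefficient(gp)[1], abs=1e-12
        )
        assert characteristic_path_length(g) == pytest.approx(
            characteristic_path_length(gp), abs=1e-12, nan_ok=True
        )
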