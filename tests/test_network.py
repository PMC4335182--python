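import itertools

import networkx as nx
import numpy as np
import pytest

from jointfc import (
    BrainNetwork,
    characteristic_path_length,
    clustering_coefficient,
    compute_network_metrics,
    identify_hubs,
    matched_random_null,
    small_world_index,
)
from jointfc.network import _rewire


def _random_graph(rng, n_nodes, directed, p=0.45):
    g = nx.DiGraph() if directed else nx.Graph()
    g.add_nodes_from(range(n_nodes))
    for u, v in itertools.permutations(range(n_nodes), 2):
        if not directed and u > v:
            continue
        if rng.random() < p:
            g.add_edge(u, v)
    return g


def _oracle_clustering(g):
    """Triangle-enumeration oracle for the clustering convention."""
    values = {}
    directed = g.is_directed()
    for i in g.nodes:
        if directed:
            nbrs = (set(g.predecessors(i)) | set(g.successors(i))) - {i}
        else:
            nbrs = set(g.neighbors(i))
        k = len(nbrs)
        if k < 2:
            values[i] = 0.0
            continue
        links = 0
        for u in nbrs:
            for v in nbrs:
                if u != v and g.has_edge(u, v):
                    links += 1
        if not directed:
            links //= 2
            values[i] = 2 * links / (k * (k - 1))
        else:
            values[i] = links / (k * (k - 1))
    return values, float(np.mean(list(values.values())))


def _oracle_path_length(g):
    """Floyd-Warshall oracle for mean shortest-path over reachable pairs."""
    nodes = list(g.nodes)
    n = len(nodes)
    idx = {node: i for i, node in enumerate(nodes)}
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for u, v in g.edges:
        dist[idx[u], idx[v]] = 1.0
        if not g.is_directed():
            dist[idx[v], idx[u]] = 1.0
    for k in range(n):
        dist = np.minimum(dist, dist[:, [k]] + dist[[k], :])
    off = dist[~np.eye(n, dtype=bool)]
    finite = off[np.isfinite(off)]
    return float(finite.mean()) if finite.size else None


class TestClusteringCoefficient:
    def test_undirected_triangle(self):
        net = BrainNetwork(["a", "b", "c"], [("a", "b"), ("b", "c"), ("a", "c")])
        _, C = clustering_coefficient(net)
        assert C == 1.0

    def test_undirected_star_has_no_triangles(self):
        net = BrainNetwork(
            ["h", "x", "y", "z"], [("h", "x"), ("h", "y"), ("h", "z")]
        )
        _, C = clustering_coefficient(net)
        assert C == 0.0

    def test_directed_three_cycle(self):
        net = BrainNetwork(
            ["a", "b", "c"], [("a", "b"), ("b", "c"), ("c", "a")], directed=True
        )
        per_node, C = clustering_coefficient(net)
        assert all(v == pytest.approx(0.5) for v in per_node.values())
        assert C == pytest.approx(0.5)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            clustering_coefficient(BrainNetwork([], []))

    @pytest.mark.parametrize("directed", [False, True])
    def test_matches_enumeration_oracle_on_small_graphs(self, rng, directed):
        for trial in range(25):
            n = int(rng.integers(3, 8))
            g = _random_graph(rng, n, directed)
            oracle_nodes, oracle_mean = _oracle_clustering(g)
            per_node, mean = clustering_coefficient(g)
            assert mean == pytest.approx(oracle_mean)
            for node in g.nodes:
                assert per_node[node] == pytest.approx(oracle_nodes[node])


class TestCharacteristicPathLength:
    def test_complete_graph(self):
        g = nx.complete_graph(4)
        assert characteristic_path_length(g) == 1.0

    def test_three_node_path(self):
        net = BrainNetwork(["a", "b", "c"], [("a", "b"), ("b", "c")])
        assert characteristic_path_length(net) == pytest.approx(4 / 3)

    def test_disconnected_components_excluded(self):
        net = BrainNetwork(
            ["a", "b", "c", "d"], [("a", "b"), ("c", "d")]
        )
        assert characteristic_path_length(net) == 1.0

    def test_no_reachable_pairs_rejected(self):
        g = nx.empty_graph(3)
        with pytest.raises(ValueError):
            characteristic_path_length(g)

    @pytest.mark.parametrize("directed", [False, True])
    def test_matches_floyd_warshall_oracle(self, rng, directed):
        for trial in range(25):
            n = int(rng.integers(3, 8))
            g = _random_graph(rng, n, directed)
            oracle = _oracle_path_length(g)
            if oracle is None:
                continue
            assert characteristic_path_length(g) == pytest.approx(oracle)


class TestMatchedRandomNull:
    @pytest.mark.parametrize("directed", [False, True])
    def test_every_realization_preserves_degree_sequence(self, rng, directed):
        g0 = _random_graph(np.random.default_rng(3), 12, directed, p=0.3)
        nswap = 10 * g0.number_of_edges()
        for seed in range(20):
            g = g0.copy()
            _rewire(g, np.random.default_rng(seed), nswap, 100 * nswap)
            if directed:
                assert dict(g.in_degree()) == dict(g0.in_degree())
                assert dict(g.out_degree()) == dict(g0.out_degree())
            else:
                assert dict(g.degree()) == dict(g0.degree())
            assert g.number_of_edges() == g0.number_of_edges()
            assert nx.number_of_selfloops(g) == 0

    def test_four_cycle_stays_two_regular(self):
        g = nx.cycle_graph(4)
        for seed in range(10):
            h = g.copy()
            _rewire(h, np.random.default_rng(seed), 40, 4000)
            assert sorted(d for _, d in h.degree()) == [2, 2, 2, 2]

    def test_null_means_match_large_ensemble_oracle(self):
        g = nx.gnm_random_graph(20, 50, seed=4)
        c_small, l_small = matched_random_null(g, n_realizations=150, seed=0)
        c_big, l_big = matched_random_null(g, n_realizations=600, seed=1)
        # two independent ensembles agree within their spread
        assert c_small == pytest.approx(c_big, rel=0.15)
        assert l_small == pytest.approx(l_big, rel=0.05)

    def test_too_few_edges_rejected(self):
        g = nx.Graph([("a", "b")])
        with pytest.raises(ValueError):
            matched_random_null(g, n_realizations=2, seed=0)


class TestSmallWorldIndex:
    def test_printed_network_summary(self):
        # undirected task network: C=0.02, L=3.24 against degree-matched
        # null averages 8.04e-4 and 4.58
        sigma = small_world_index(0.02, 3.24, 8.04e-4, 4.58)
        assert round(sigma, 2) == 35.16

    def test_identity_when_equal_to_null(self):
        assert small_world_index(0.3, 2.0, 0.3, 2.0) == 1.0

    def test_scale_consistency(self):
        a = small_world_index(0.02, 3.0, 0.004, 3.3)
        b = small_world_index(0.02 * 7, 3.0, 0.004 * 7, 3.3)
        assert a == pytest.approx(b)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            small_world_index(0.1, 2.0, 0.0, 3.0)


class TestIdentifyHubs:
    def test_population_sd_threshold(self):
        # degrees [5,1,1,1,1,1]: mean 1.667, population SD 1.491 -> cut 3.157
        g = nx.star_graph(5)
        hubs = identify_hubs(g)
        assert hubs["hubs"] == [0]

    def test_regular_graph_has_no_hubs(self):
        g = nx.cycle_graph(6)
        assert identify_hubs(g)["hubs"] == []

    def test_directed_star_driving_hub(self):
        g = nx.DiGraph([(0, 1), (0, 2), (0, 3), (0, 4)])
        hubs = identify_hubs(g)
        assert hubs["driving_hubs"] == [0]
        assert hubs["driven_hubs"] == []
        assert hubs["hubs"] == [0]

    def test_invariant_under_relabelling(self, rng):
        g = _random_graph(rng, 10, directed=False, p=0.3)
        mapping = {i: f"node{(i * 7) % 10}" for i in g.nodes}
        relabeled = nx.relabel_nodes(g, mapping)
        original = identify_hubs(g)["hubs"]
        assert sorted(mapping[n] for n in original) == identify_hubs(relabeled)["hubs"]


class TestNetworkMetricsReport:
    def test_full_report_fields(self):
        g = nx.gnm_random_graph(15, 40, seed=2)
        metrics = compute_network_metrics(g, n_null=50, seed=7)
        assert 0.0 <= metrics.clustering <= 1.0
        assert metrics.path_length >= 1.0
        assert metrics.small_world == pytest.approx(
            (metrics.clustering / metrics.c_random)
            / (metrics.path_length / metrics.l_random)
        )
        payload = metrics.to_dict()
        assert payload["n_null"] == 50 and payload["null_seed"] == 7

    def test_network_container_validation(self):
        with pytest.raises(ValueError, match="self-loop"):
            BrainNetwork(["a"], [("a", "a")])
        with pytest.raises(ValueError, match="duplicate"):
            BrainNetwork(["a", "b"], [("a", "b"), ("b", "a")])
        # but opposite arcs are distinct edges in a directed network
        BrainNetwork(["a", "b"], [("a", "b"), ("b", "a")], directed=True)
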