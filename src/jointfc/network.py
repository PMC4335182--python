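"""Graph-theoretic characterization of inferred brain networks.

From the called edges we build an undirected coherence network and a
directed ascendancy network, then describe their topology by the mean
clustering coefficient C, the characteristic path length L, a small-world
index sigma = (C/C_random)/(L/L_random) computed against degree-matched
rewired null networks, and hub sets (nodes whose degree exceeds the
network mean by more than one standard deviation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "BrainNetwork",
    "NetworkMetrics",
    "build_network",
    "clustering_coefficient",
    "characteristic_path_length",
    "matched_random_null",
    "small_world_index",
    "identify_hubs",
    "compute_network_metrics",
]


@dataclass
class BrainNetwork:
    """A node/edge graph; directed edges ``(a, b)`` mean a ascendant to b."""

    nodes: list
    edges: list
    directed: bool = False

    def __post_init__(self) -> None:
        seen = set()
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop at node {a!r}")
            key = (a, b) if self.directed else frozenset((a, b))
            if key in seen:
                raise ValueError(f"duplicate edge {(a, b)!r}")
            seen.add(key)
        node_set = set(self.nodes)
        for a, b in self.edges:
            if a not in node_set or b not in node_set:
                raise ValueError(f"edge {(a, b)!r} references unknown node")

    def to_networkx(self) -> nx.Graph | nx.DiGraph:
        g = nx.DiGraph() if self.directed else nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


def build_network(edge_calls, directed: bool = False) -> BrainNetwork:
    """Assemble a network from edge-inference results.

    Undirected: all connected pairs.  Directed: connected pairs with a
    direction call, oriented from the ascendant region.  Nodes are the
    regions incident to at least one retained edge.
    """
    edges = []
    for e in edge_calls:
        if not e.connected:
            continue
        if not directed:
            edges.append(tuple(e.pair))
        elif e.direction == "a->b":
            edges.append((e.pair[0], e.pair[1]))
        elif e.direction == "b->a":
            edges.append((e.pair[1], e.pair[0]))
    nodes = sorted({n for edge in edges for n in edge})
    return BrainNetwork(nodes=nodes, edges=edges, directed=directed)


def _as_graph(graph) -> nx.Graph | nx.DiGraph:
    if isinstance(graph, BrainNetwork):
        return graph.to_networkx()
    return graph


def clustering_coefficient(graph) -> tuple[dict, float]:
    """Per-node and mean clustering coefficient.

    Undirected: C_i = 2 E_i / (k_i (k_i - 1)) with E_i the number of edges
    among the k_i neighbors of i.  Directed: k_i counts distinct neighbors
    (union of in- and out-neighborhoods) and E_i counts directed links
    among them, giving C_i = E_i / (k_i (k_i - 1)).  Nodes with fewer than
    two neighbors contribute C_i = 0.  C is the mean over all nodes.
    """
    g = _as_graph(graph)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    per_node: dict = {}
    if not g.is_directed():
        per_node = nx.clustering(g)
    else:
        for i in g.nodes:
            nbrs = set(g.predecessors(i)) | set(g.successors(i))
            nbrs.discard(i)
            k = len(nbrs)
            if k < 2:
                per_node[i] = 0.0
                continue
            links = sum(1 for u in nbrs for v in nbrs if u != v and g.has_edge(u, v))
            per_node[i] = links / (k * (k - 1))
    return per_node, float(np.mean(list(per_node.values())))


def characteristic_path_length(graph) -> float:
    """Mean shortest-path length over ordered reachable node pairs.

    Directions are respected in directed graphs; pairs with no connecting
    path are excluded from the average rather than treated as infinite.
    """
    g = _as_graph(graph)
    total = 0.0
    count = 0
    for _, lengths in nx.all_pairs_shortest_path_length(g):
        for dist in lengths.values():
            if dist > 0:
                total += dist
                count += 1
    if count == 0:
        raise ValueError("graph has no reachable node pairs")
    return total / count


def _rewire(g, rng: np.random.Generator, n_swaps: int, max_tries: int):
    """Degree-preserving double-edge-swap rewiring (in place).

    Undirected: (u-v, x-y) -> (u-x, v-y) or (u-y, v-x); directed:
    (u->v, x->y) -> (u->y, x->v), preserving in- and out-degrees.  Swaps
    creating self-loops or duplicate edges are rejected.
    """
    directed = g.is_directed()
    edges = list(g.edges())
    done = 0
    for _ in range(max_tries):
        if done >= n_swaps:
            break
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        (u, v), (x, y) = edges[i], edges[j]
        if directed:
            new_i, new_j = (u, y), (x, v)
        else:
            if rng.random() < 0.5:
                new_i, new_j = (u, x), (v, y)
            else:
                new_i, new_j = (u, y), (v, x)
        (p, q), (r, s) = new_i, new_j
        if p == q or r == s:
            continue
        if g.has_edge(p, q) or g.has_edge(r, s):
            continue
        if not directed and (frozenset(new_i) == frozenset(new_j)):
            continue
        if directed and new_i == new_j:
            continue
        g.remove_edge(u, v)
        g.remove_edge(x, y)
        g.add_edge(p, q)
        g.add_edge(r, s)
        edges[i], edges[j] = new_i, new_j
        done += 1


def matched_random_null(
    graph, n_realizations: int = 1000, seed: int = 0, swaps_per_edge: int = 10
) -> tuple[float, float]:
    """Mean C and L over degree-matched rewired random networks.

    Each realization rewires a copy of the input by double edge swaps
    (directed swaps preserve in- and out-degrees separately), so every
    null network has exactly the original degree sequence.
    """
    g0 = _as_graph(graph)
    m = g0.number_of_edges()
    if m < 2:
        raise ValueError("null model requires at least 2 edges")
    rng = np.random.default_rng(seed)
    n_swaps = swaps_per_edge * m
    cs, ls = [], []
    for _ in range(n_realizations):
        g = g0.copy()
        _rewire(g, rng, n_swaps, max_tries=100 * n_swaps)
        _, c = clustering_coefficient(g)
        cs.append(c)
        ls.append(characteristic_path_length(g))
    return float(np.mean(cs)), float(np.mean(ls))


def small_world_index(C: float, L: float, c_random: float, l_random: float) -> float:
    """sigma = (C / C_random) / (L / L_random); sigma > 1 is small-world."""
    if c_random == 0 or l_random == 0 or L == 0:
        raise ValueError("zero denominator in small-world index")
    return (C / c_random) / (L / l_random)


def identify_hubs(graph) -> dict:
    """Nodes with degree more than one SD above the network mean degree.

    Returns ``{"hubs": [...]}`` for undirected graphs; directed graphs add
    ``driving_hubs`` (out-degree criterion) and ``driven_hubs`` (in-degree
    criterion).  The SD is the population standard deviation over all
    network nodes; with zero spread the strict inequality yields no hubs.
    """
    g = _as_graph(graph)

    def over_threshold(degrees: dict) -> list:
        values = np.array(list(degrees.values()), dtype=float)
        cut = values.mean() + values.std(ddof=0)
        return sorted(n for n, d in degrees.items() if d > cut)

    out = {"hubs": over_threshold(dict(g.degree()))}
    if g.is_directed():
        out["driving_hubs"] = over_threshold(dict(g.out_degree()))
        out["driven_hubs"] = over_threshold(dict(g.in_degree()))
    return out


@dataclass
class NetworkMetrics:
    """Topology summary of one network with its null-model context."""

    clustering: float
    path_length: float
    c_random: float
    l_random: float
    small_world: float
    degrees: dict
    hubs: list
    driving_hubs: list = field(default_factory=list)
    driven_hubs: list = field(default_factory=list)
    n_null: int = 1000
    null_seed: int = 0

    def to_dict(self) -> dict:
        return {
            "clustering": self.clustering,
            "path_length": self.path_length,
            "c_random": self.c_random,
            "l_random": self.l_random,
            "small_world": self.small_world,
            "degrees": self.degrees,
            "hubs": self.hubs,
            "driving_hubs": self.driving_hubs,
            "driven_hubs": self.driven_hubs,
            "n_null": self.n_null,
            "null_seed": self.null_seed,
        }


def compute_network_metrics(
    graph, n_null: int = 1000, seed: int = 0
) -> NetworkMetrics:
    """Full topology report: C, L, null means, sigma, degrees, hubs."""
    g = _as_graph(graph)
    _, C = clustering_coefficient(g)
    L = characteristic_path_length(g)
    c_rand, l_rand = matched_random_null(g, n_realizations=n_null, seed=seed)
    sigma = small_world_index(C, L, c_rand, l_rand)
    hubs = identify_hubs(g)
    return NetworkMetrics(
        clustering=C,
        path_length=L,
        c_random=c_rand,
        l_random=l_rand,
        small_world=sigma,
        degrees={n: d for n, d in g.degree()},
        hubs=hubs["hubs"],
        driving_hubs=hubs.get("driving_hubs", []),
        driven_hubs=hubs.get("driven_hubs", []),
        n_null=n_null,
        null_seed=seed,
    )
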