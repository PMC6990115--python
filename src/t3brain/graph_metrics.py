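"""Nodal graph metrics, efficiency measures, and community detection.

All metrics operate on binarized (unweighted, undirected) networks.  The
three nodal metrics — degree centrality, betweenness centrality, and the
Watts-Strogatz clustering coefficient — are the network features entering
the three-way analysis; the efficiency measures and community detection
serve the cost-threshold selection criteria.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .connectivity import BinaryNetwork

METRIC_NAMES = ("degree", "betweenness", "clustering")


@dataclass
class NodeMetricVector:
    """Per-node values of one nodal metric at one network cost."""

    values: np.ndarray
    metric: str
    cost: float


@dataclass
class CommunityPartition:
    """Modularity-based partition: labels are contiguous 1..n_communities."""

    labels: np.ndarray
    n_communities: int
    gamma: float
    modularity: float


def _to_graph(net: BinaryNetwork) -> nx.Graph:
    G = nx.from_numpy_array(np.asarray(net.adjacency))
    G.add_nodes_from(range(net.n_nodes))
    return G


def degree_centrality(net: BinaryNetwork) -> NodeMetricVector:
    """Number of edges incident on each node (row sums of the adjacency)."""
    values = np.asarray(net.adjacency).sum(axis=1).astype(float)
    return NodeMetricVector(values, "degree", net.cost)


def betweenness_centrality(net: BinaryNetwork) -> NodeMetricVector:
    """Fraction of shortest paths between other node pairs passing through
    each node, normalized by (J-1)(J-2)/2.  Unreachable pairs contribute 0."""
    G = _to_graph(net)
    bc = nx.betweenness_centrality(G, normalized=True)
    values = np.array([bc[v] for v in range(net.n_nodes)])
    return NodeMetricVector(values, "betweenness", net.cost)


def clustering_coefficient(net: BinaryNetwork) -> NodeMetricVector:
    """Watts-Strogatz local clustering coefficient.

    For node v with degree d >= 2 this is 2*(edges among neighbours of v) /
    (d*(d-1)); nodes with degree < 2 get 0.
    """
    G = _to_graph(net)
    cc = nx.clustering(G)
    values = np.array([cc[v] for v in range(net.n_nodes)])
    return NodeMetricVector(values, "clustering", net.cost)


def global_efficiency(net: BinaryNetwork) -> float:
    """Mean of 1/d(i, j) over ordered pairs i != j; disconnected pairs add 0."""
    return nx.global_efficiency(_to_graph(net))


def local_efficiency(net: BinaryNetwork) -> float:
    """Mean over nodes of the global efficiency of each node's
    neighbour-induced subgraph; nodes of degree < 2 contribute 0."""
    return nx.local_efficiency(_to_graph(net))


def newman_communities(net: BinaryNetwork, gamma: float = 1.0) -> CommunityPartition:
    """Greedy agglomerative maximization of resolution-parameterized modularity.

    ``gamma > 1`` favours smaller modules, ``gamma < 1`` larger ones.  The
    merge order is deterministic, so identical inputs give identical
    partitions.  A graph with no edges returns each node as its own
    community with modularity 0.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    G = _to_graph(net)
    if G.number_of_edges() == 0:
        labels = np.arange(1, net.n_nodes + 1)
        return CommunityPartition(labels, net.n_nodes, gamma, 0.0)
    comms = nx.community.greedy_modularity_communities(G, resolution=gamma)
    # stable labelling: communities ordered by their smallest node index
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    labels = np.empty(net.n_nodes, dtype=int)
    for lab, members in enumerate(comms, start=1):
        for v in members:
            labels[v] = lab
    q = nx.community.modularity(G, [set(c) for c in comms], resolution=gamma)
    return CommunityPartition(labels, len(comms), gamma, q)


def _ring_lattice_adjacency(J: int, m: int) -> np.ndarray:
    """Ring lattice on J nodes with exactly m edges.

    Full rings of increasing neighbour distance are added first; the
    remaining edges are placed at the next ring distance on nodes
    0, 1, ... in order, which makes the construction deterministic.
    """
    adj = np.zeros((J, J), dtype=np.int8)
    remaining = m
    d = 1
    while remaining > 0 and d <= J // 2:
        ring = [(i, (i + d) % J) for i in range(J)]
        if d * 2 == J:  # antipodal ring has only J/2 distinct edges
            ring = ring[: J // 2]
        ring = [e for e in ring if adj[e[0], e[1]] == 0]
        take = ring if len(ring) <= remaining else ring[:remaining]
        for a, b in take:
            adj[a, b] = adj[b, a] = 1
        remaining -= len(take)
        d += 1
    if remaining > 0:
        raise ValueError(f"cannot place {m} edges on a {J}-node lattice")
    return adj


def reference_graph(
    net: BinaryNetwork,
    kind: str,
    n_realizations: int = 1,
    seed: int | None = None,
) -> list[BinaryNetwork]:
    """Null-model reference networks for the small-world criterion.

    kind="random": degree-preserving randomization via double-edge swaps
    (10 x edge_count attempted swaps per realization).  kind="lattice": a
    deterministic ring lattice with the same node and edge count (all
    realizations identical).
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    if kind not in ("random", "lattice"):
        raise ValueError(f"unknown reference kind {kind!r}")
    J, m = net.n_nodes, net.edge_count
    out = []
    if kind == "lattice":
        adj = _ring_lattice_adjacency(J, m)
        return [BinaryNetwork(adj, net.cost, list(net.region_names)) for _ in range(n_realizations)]
    rng = np.random.default_rng(seed)
    for _ in range(n_realizations):
        G = _to_graph(net)
        if m >= 2 and J >= 4:
            try:
                nx.double_edge_swap(
                    G,
                    nswap=10 * m,
                    max_tries=200 * m + 100,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            except nx.NetworkXError:
                pass  # e.g. complete graphs admit no swap; keep as-is
            except nx.NetworkXAlgorithmError:
                pass
        adj = nx.to_numpy_array(G, nodelist=range(J), dtype=np.int8)
        out.append(BinaryNetwork(adj, net.cost, list(net.region_names)))
    return out
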