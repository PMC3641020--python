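"""Node centralities and global topology statistics.

All measures follow the conventions of classical network analysis software
on simple, undirected, unweighted graphs:

* degree ``k``: number of incident edges;
* betweenness centrality ``BC(v) = sum_{s!=t!=v} sigma_st(v)/sigma_st``
  normalized by ``2/((N-1)(N-2))`` so that the centre of a star scores 1
  (endpoints are excluded);
* closeness centrality ``CC(v) = (N-1) / sum_u d(v, u)``;
* diameter ``D``: the longest shortest path, in integer steps;
* mean shortest path length ``mspl``: mean pairwise distance over
  unordered node pairs, self-distances excluded.

Interaction confidence scores are used upstream only as an inclusion
filter; shortest paths here are always unweighted. Betweenness and
closeness require a connected graph — callers pass the giant component,
and a disconnected input raises rather than silently switching to a
harmonic variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .graph_model import DisconnectedGraphError, EmptyNetworkError


@dataclass(frozen=True)
class NetworkStats:
    """Global measurements of a connected graph."""

    n: int
    e: int
    avg_degree: float
    diameter: int
    mspl: float


def _require_connected(net: nx.Graph, what: str) -> None:
    if net.number_of_nodes() == 0:
        raise EmptyNetworkError(f"{what}: empty graph")
    if not nx.is_connected(net):
        raise DisconnectedGraphError(
            f"{what} requires a connected graph; extract the giant "
            "component first (graph_model.giant_component)"
        )


def degree(net: nx.Graph) -> dict[str, int]:
    """Degree of every node."""
    return dict(net.degree())


def betweenness(net: nx.Graph) -> dict[str, float]:
    """Normalized betweenness centrality of every node (Brandes algorithm).

    Values lie in [0, 1]; the centre of a star attains 1. For graphs with
    fewer than 3 nodes all values are 0.
    """
    _require_connected(net, "betweenness")
    return nx.betweenness_centrality(net, normalized=True, weight=None)


def closeness(net: nx.Graph) -> dict[str, float]:
    """Closeness centrality (N-1 over the sum of distances to all others)."""
    _require_connected(net, "closeness")
    if net.number_of_nodes() == 1:
        return {n: 0.0 for n in net.nodes}
    return nx.closeness_centrality(net)


def global_stats(net: nx.Graph) -> NetworkStats:
    """N, E, average degree 2E/N, diameter and mean shortest path length."""
    _require_connected(net, "global_stats")
    n = net.number_of_nodes()
    e = net.number_of_edges()
    if n == 1:
        return NetworkStats(1, e, 2 * e / n, 0, 0.0)
    diam = 0
    total = 0
    for _, dists in nx.all_pairs_shortest_path_length(net):
        row_max = max(dists.values())
        diam = max(diam, row_max)
        total += sum(dists.values())
    # each unordered pair counted twice in the ordered sum
    mspl = total / (n * (n - 1))
    return NetworkStats(n, e, 2 * e / n, diam, mspl)
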