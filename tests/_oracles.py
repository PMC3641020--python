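"""Independent brute-force oracles for small graphs (<= ~10 nodes).

These deliberately avoid every algorithm used by the package: shortest
paths are found by exhaustive depth-first enumeration of all simple
paths, and centralities are computed straight from their definitions.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx


def all_simple_paths(net: nx.Graph, s, t):
    """Every simple s-t path, by explicit DFS."""
    out = []

    def walk(node, visited, path):
        if node == t:
            out.append(tuple(path))
            return
        for nb in net.neighbors(node):
            if nb not in visited:
                visited.add(nb)
                path.append(nb)
                walk(nb, visited, path)
                path.pop()
                visited.remove(nb)

    walk(s, {s}, [s])
    return out


def all_shortest_paths(net: nx.Graph, s, t):
    paths = all_simple_paths(net, s, t)
    if not paths:
        return []
    d = min(len(p) for p in paths)
    return [p for p in paths if len(p) == d]


def distance(net: nx.Graph, s, t) -> int:
    sp = all_shortest_paths(net, s, t)
    if not sp:
        raise ValueError(f"no path {s}-{t}")
    return len(sp[0]) - 1


def betweenness_oracle(net: nx.Graph) -> dict:
    """Normalized betweenness from the definition: for every unordered
    pair s != t, the fraction of shortest s-t paths through v (endpoints
    excluded), scaled by 2/((N-1)(N-2))."""
    nodes = sorted(net.nodes)
    n = len(nodes)
    raw = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        sp = all_shortest_paths(net, s, t)
        if not sp:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            raw[v] += sum(1 for p in sp if v in p) / len(sp)
    if n < 3:
        return {v: 0.0 for v in nodes}
    norm = 2.0 / ((n - 1) * (n - 2))
    return {v: raw[v] * norm for v in nodes}


def closeness_oracle(net: nx.Graph) -> dict:
    """(N-1) / sum of shortest-path distances, distances by enumeration."""
    nodes = sorted(net.nodes)
    n = len(nodes)
    out = {}
    for v in nodes:
        total = sum(distance(net, v, u) for u in nodes if u != v)
        out[v] = (n - 1) / total if total else 0.0
    return out


def stats_oracle(net: nx.Graph):
    """(diameter, mspl) from the enumerated distance matrix."""
    nodes = sorted(net.nodes)
    dists = [distance(net, s, t) for s, t in combinations(nodes, 2)]
    return max(dists), sum(dists) / len(dists)


def random_connected_graph(rng, n: int) -> nx.Graph:
    """Small random connected simple graph: random tree + random extras."""
    g = nx.Graph()
    nodes = [f"N{i}" for i in range(n)]
    g.add_node(nodes[0])
    for i in range(1, n):
        g.add_edge(nodes[i], nodes[int(rng.integers(i))])
    n_extra = int(rng.integers(0, n))
    for _ in range(n_extra):
        i, j = rng.integers(n, size=2)
        if i != j:
            g.add_edge(nodes[int(i)], nodes[int(j)])
    return g
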