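"""High-betweenness backbone, key-node classification, and the
all-shortest-paths seed subnetwork.

The backbone is the induced subgraph on the top 5% of nodes by betweenness
in the giant component — the "heavily used intersections" of the network
viewed as a transportation system. Key nodes are classified on the two
top-fraction sets (hubs by degree, bottlenecks by betweenness) into the
four classes of Yu et al.: hub-bottleneck, hub-nonbottleneck,
nonhub-bottleneck, nonhub-nonbottleneck.

The seed subnetwork collects the vertices of *all* distinct shortest paths
between every pair of seed genes (not one representative path per pair)
and takes the induced subgraph on them: the smallest vertex set in which
every seed pair remains connected at its original distance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import networkx as nx

from . import centrality
from .graph_model import PpinetError, induced_subgraph, seeds_of

logger = logging.getLogger(__name__)

KEY_NODE_CLASSES = (
    "hub-bottleneck",
    "hub-nonbottleneck",
    "nonhub-bottleneck",
    "nonhub-nonbottleneck",
)


class PathExplosionError(PpinetError):
    """Shortest-path count between one pair exceeded the configured cap."""


def cutoff_count(n_total: int, fraction: float = 0.05) -> int:
    """Size of a top-fraction cut: ``ceil(fraction * n_total)``.

    With the conventional 5% criterion and a 535-node giant component this
    gives 27.
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    return math.ceil(fraction * n_total)


def select_top_fraction(
    values: Mapping[str, float],
    n_total: int,
    fraction: float = 0.05,
) -> list[str]:
    """The ``ceil(fraction * n_total)`` highest-scoring nodes.

    Output is ordered by score descending, ties by symbol. Ties *at the
    boundary* are all included, so the result may exceed the nominal
    cutoff; inflation is logged.
    """
    if not values:
        raise ValueError("empty score map")
    m = min(cutoff_count(n_total, fraction), len(values))
    ranked = sorted(values, key=lambda n: (-values[n], n))
    boundary = values[ranked[m - 1]]
    out = ranked[:m]
    for n in ranked[m:]:
        if values[n] == boundary:
            out.append(n)
        else:
            break
    if len(out) > m:
        logger.info("top-fraction boundary tie: %d nodes kept for nominal cutoff %d",
                    len(out), m)
    return out


@dataclass
class BackboneResult:
    """Ranked high-BC node set and its induced subgraph."""

    cutoff: int
    members: list[tuple[str, float]]
    backbone_net: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return [n for n, _ in self.members]


def extract_backbone(
    giant: nx.Graph,
    bc: Mapping[str, float],
    fraction: float = 0.05,
) -> BackboneResult:
    """Induced subgraph of the giant component on its top-fraction BC nodes.

    The backbone may itself be disconnected; it is reported as-is.
    """
    top = select_top_fraction(bc, giant.number_of_nodes(), fraction)
    return BackboneResult(
        cutoff=cutoff_count(giant.number_of_nodes(), fraction),
        members=[(n, bc[n]) for n in top],
        backbone_net=induced_subgraph(giant, top),
    )


@dataclass
class KeyNodeClassification:
    """Four-way hub/bottleneck partition plus the three report sets."""

    labels: dict[str, str]
    hubs: list[str]           # top-fraction by degree, ranked
    bottlenecks: list[str]    # top-fraction by BC, ranked

    @property
    def hub_bottlenecks(self) -> list[str]:
        return [n for n in self.bottlenecks if self.labels[n] == "hub-bottleneck"]

    @property
    def bottleneck_only(self) -> list[str]:
        return [n for n in self.bottlenecks if self.labels[n] == "nonhub-bottleneck"]

    @property
    def hub_only(self) -> list[str]:
        return [n for n in self.hubs if self.labels[n] == "hub-nonbottleneck"]

    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in KEY_NODE_CLASSES}
        for lab in self.labels.values():
            out[lab] += 1
        return out


def classify_key_nodes(
    degree: Mapping[str, int],
    bc: Mapping[str, float],
    n_total: int,
    fraction: float = 0.05,
) -> KeyNodeClassification:
    """Label every node by membership in the top-fraction degree and BC sets."""
    if set(degree) != set(bc):
        raise ValueError("degree and betweenness maps cover different node sets")
    hubs = select_top_fraction(dict(degree), n_total, fraction)
    bottlenecks = select_top_fraction(dict(bc), n_total, fraction)
    hub_set, bn_set = set(hubs), set(bottlenecks)
    labels = {}
    for n in degree:
        h, b = n in hub_set, n in bn_set
        labels[n] = ("hub-bottleneck" if h and b
                     else "hub-nonbottleneck" if h
                     else "nonhub-bottleneck" if b
                     else "nonhub-nonbottleneck")
    return KeyNodeClassification(labels, hubs, bottlenecks)


@dataclass
class SeedSubnetwork:
    """Union of all shortest paths between seed pairs, as an induced graph."""

    nodes: set[str]
    net: nx.Graph
    bc_ranking: list[tuple[str, float]]
    # per-pair inventory: (seed_a, seed_b) -> list of paths (node tuples)
    paths: dict[tuple[str, str], list[tuple[str, ...]]] = field(default_factory=dict)

    def composition(self, backbone_nodes: Sequence[str]) -> dict[str, int]:
        """Partition members into seed/backbone categories.

        Returns counts for: seeds that are also backbone nodes, seed-only,
        backbone-only, and connector nodes that are neither (plus the
        total), mirroring the published bookkeeping of the subnetwork.
        """
        seeds = seeds_of(self.net)
        bb = set(backbone_nodes)
        both = len(seeds & bb & self.nodes)
        seed_only = len((seeds - bb) & self.nodes)
        bb_only = len((bb - seeds) & self.nodes)
        other = len(self.nodes - seeds - bb)
        return {
            "seed_and_backbone": both,
            "seed_only": seed_only,
            "backbone_only": bb_only,
            "connector": other,
            "total": both + seed_only + bb_only + other,
        }


def seed_shortest_path_subnetwork(
    giant: nx.Graph,
    seeds: Sequence[str] | None = None,
    path_cap: int = 100_000,
) -> SeedSubnetwork:
    """Collect every distinct shortest path between every pair of seeds.

    ``seeds`` defaults to the flagged seeds of ``giant``; seeds not present
    in the graph are ignored by the caller's contract (the giant component
    is where all analysis happens). The subnetwork is the induced subgraph
    on the union of path vertices — induced edges among collected nodes are
    kept, not only path edges. Betweenness is recomputed within it.

    ``path_cap`` bounds the number of distinct shortest paths enumerated
    for any single pair; exceeding it raises :class:`PathExplosionError`
    rather than silently sampling.
    """
    if seeds is None:
        present = sorted(seeds_of(giant))
    else:
        present = sorted(set(seeds) & set(giant.nodes))
    if len(present) < 2:
        raise ValueError("need at least two seeds present in the giant component")

    members: set[str] = set(present)
    inventory: dict[tuple[str, str], list[tuple[str, ...]]] = {}
    for a, b in combinations(present, 2):
        pair_paths: list[tuple[str, ...]] = []
        for i, p in enumerate(nx.all_shortest_paths(giant, a, b)):
            if i >= path_cap:
                raise PathExplosionError(
                    f"more than {path_cap} shortest paths between {a} and {b}; "
                    "raise path_cap explicitly to proceed"
                )
            pair_paths.append(tuple(p))
            members.update(p)
        inventory[(a, b)] = pair_paths

    net = induced_subgraph(giant, members)
    bc = centrality.betweenness(net)
    ranking = sorted(bc.items(), key=lambda kv: (-kv[1], kv[0]))
    return SeedSubnetwork(nodes=members, net=net, bc_ranking=ranking,
                          paths=inventory)
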