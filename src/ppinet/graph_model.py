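"""Core graph model: extended-network construction and component handling.

The central object is a plain :class:`networkx.Graph` over protein symbols
(upper-cased strings), with a boolean ``seed`` attribute on every node
marking the disease-gene seeds. All graphs are simple and undirected:
self-interactions and duplicate rows are removed at ingest (see
:mod:`ppinet.io_formats`), and no operation here ever introduces them.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

_SYMBOL_RE = re.compile(r"^\S+$")


class PpinetError(Exception):
    """Base class for all errors raised by this package."""


class EmptyNetworkError(PpinetError):
    """Raised when a construction step yields a network with no nodes."""


class DisconnectedGraphError(PpinetError):
    """Raised when an operation requiring a connected graph receives one
    with more than one component (extract the giant component first)."""


def normalize_symbol(symbol: str) -> str:
    """Canonicalize a protein/gene symbol: strip whitespace, upper-case.

    Raises :class:`ValueError` on empty or whitespace-containing tokens.
    """
    s = str(symbol).strip().upper()
    if not s or not _SYMBOL_RE.match(s):
        raise ValueError(f"malformed protein identifier: {symbol!r}")
    return s


@dataclass
class InteractionTable:
    """A cleaned, weighted undirected edge list.

    ``rows`` holds ``(id_a, id_b, score)`` triples with ``id_a < id_b``
    lexicographically, no self-pairs, no duplicates (reverse duplicates are
    merged keeping the maximum score). Scores are on the canonical 0-1000
    STRING combined-score scale.
    """

    rows: list[tuple[str, str, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def filtered(self, min_score: float) -> "InteractionTable":
        """Rows with score >= ``min_score``."""
        return InteractionTable([r for r in self.rows if r[2] >= min_score])

    def cleaned(self) -> "InteractionTable":
        """Apply the canonical cleaning rules (idempotent).

        Self-pairs dropped; (a, b) and (b, a) merged into the sorted pair
        keeping the maximum score; rows sorted for determinism.
        """
        best: dict[tuple[str, str], float] = {}
        for a, b, s in self.rows:
            a, b = normalize_symbol(a), normalize_symbol(b)
            if a == b:
                continue
            key = (a, b) if a < b else (b, a)
            if s < 0:
                raise ValueError(f"negative interaction score {s} for {key}")
            if key not in best or s > best[key]:
                best[key] = float(s)
        return InteractionTable(sorted((a, b, s) for (a, b), s in best.items()))


@dataclass
class ComponentDecomposition:
    """Connected components ordered by size descending (ties broken by the
    lexicographically smallest member), with ``giant`` the first."""

    components: list[set[str]]

    @property
    def giant(self) -> set[str]:
        return self.components[0]

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.components]


def _as_seed_graph(nodes: Iterable[str], edges: Iterable[tuple[str, str]],
                   seeds: Iterable[str]) -> nx.Graph:
    g = nx.Graph()
    seed_set = set(seeds)
    for n in nodes:
        g.add_node(n, seed=(n in seed_set))
    for a, b in edges:
        if a != b:
            g.add_edge(a, b)
    return g


def seeds_of(net: nx.Graph) -> set[str]:
    """The nodes flagged as seeds."""
    return {n for n, d in net.nodes(data=True) if d.get("seed", False)}


def build_extended_network(
    seeds: Sequence[str],
    interactions: InteractionTable,
    min_score: float = 400.0,
    keep_missing_seeds: bool = False,
) -> nx.Graph:
    """Build the extended network: seeds, their direct interaction partners,
    and *all* interactions among that node set.

    The node set is the seeds found in the (score-filtered) table plus every
    direct neighbour of a seed; the edge set is induced, i.e. it includes
    neighbour-neighbour interactions, not only seed-incident ones. Seeds
    absent from the filtered table are kept as isolated flagged nodes when
    ``keep_missing_seeds`` is true, otherwise dropped with a warning.

    Raises :class:`EmptyNetworkError` if nothing survives.
    """
    if not seeds:
        raise ValueError("seed list is empty")
    seed_set = {normalize_symbol(s) for s in seeds}
    kept = interactions.cleaned().filtered(min_score)

    full = nx.Graph()
    full.add_weighted_edges_from(kept.rows)

    present = seed_set & set(full.nodes)
    missing = sorted(seed_set - present)
    if missing:
        action = "kept as isolated nodes" if keep_missing_seeds else "dropped"
        logger.warning(
            "%d seed(s) absent from the interaction table at min_score=%s (%s): %s",
            len(missing), min_score, action, ", ".join(missing),
        )

    members = set(present)
    for s in present:
        members.update(full.neighbors(s))

    edges = [(a, b) for a, b in full.edges if a in members and b in members]
    if keep_missing_seeds:
        members |= set(missing)

    if not members:
        raise EmptyNetworkError(
            "extended network is empty: no seed appears in the interaction "
            f"table at min_score={min_score}"
        )
    return _as_seed_graph(sorted(members), edges, seed_set)


def decompose_components(net: nx.Graph) -> ComponentDecomposition:
    """Partition ``net`` into connected components, largest first.

    Equal-size components are ordered by their lexicographically smallest
    member, so the decomposition (and hence the giant) is deterministic.
    """
    if net.number_of_nodes() == 0:
        raise EmptyNetworkError("cannot decompose an empty network")
    comps = [set(c) for c in nx.connected_components(net)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return ComponentDecomposition(comps)


def giant_component(net: nx.Graph) -> nx.Graph:
    """Convenience: the induced subgraph on the largest component."""
    return induced_subgraph(net, decompose_components(net).giant)


def induced_subgraph(net: nx.Graph, keep: Iterable[str]) -> nx.Graph:
    """Induced subgraph on ``keep``; seed flags preserved.

    Raises :class:`KeyError` naming the offending ids if ``keep`` is not a
    subset of the node set.
    """
    keep = set(keep)
    unknown = keep - set(net.nodes)
    if unknown:
        raise KeyError(
            f"nodes not in network: {', '.join(sorted(unknown))}"
        )
    sub = nx.Graph()
    for n in sorted(keep):
        sub.add_node(n, **net.nodes[n])
    sub.add_edges_from((a, b) for a, b in net.edges if a in keep and b in keep)
    return sub
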