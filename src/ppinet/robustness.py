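"""Seed-omission robustness protocol.

To test whether the backbone and its central protein are artefacts of the
particular seed list, the protocol rebuilds the extended network from
perturbed seed lists ("test networks") and asks two questions of each:
which node has the largest betweenness, and how many of its top-M BC
nodes belong to the reference backbone (M = the reference backbone size,
frozen — not recomputed per test network).

The omission plan follows the published design: with k the number of
omitted seeds,

* k = 1: every seed omitted once (one configuration per seed);
* k = 2: the central gene paired with every other seed;
* k >= 3: the central gene plus k-1 seeds drawn uniformly without
  replacement, a fixed number of independent draws per k (repeats across
  draws permitted).

With 69 seeds, k up to 7 and 30 draws per k this yields
69 + 68 + 5*30 = 287 test networks. Crucially, an omitted seed may
re-enter a test network as a direct neighbour of the remaining seeds —
this is how the central protein can top the betweenness ranking of
networks it did not seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import centrality, graph_model
from .graph_model import InteractionTable
from .io_formats import SeedList


@dataclass
class OmissionPlan:
    """Enumerated omitted-seed configurations, grouped by omitted count k."""

    groups: dict[int, list[frozenset[str]]]
    central_gene: str
    draws_per_k: int
    rng_seed: int

    @property
    def n_configurations(self) -> int:
        return sum(len(v) for v in self.groups.values())

    def __iter__(self):
        for k in sorted(self.groups):
            for omitted in self.groups[k]:
                yield k, omitted


def ordered_omission_count(n_seeds: int, k: int) -> int:
    """Number of *ordered* ways to omit k of n seeds: n!/(n-k)!.

    This is the combinatorial count motivating random sampling for k >= 3
    (69 * 68 * 67 = 314364 for the published list).
    """
    return math.perm(n_seeds, k)


def build_omission_plan(
    seeds: SeedList | Sequence[str],
    central: str,
    k_max: int = 7,
    draws_per_k: int = 30,
    rng_seed: int = 0,
) -> OmissionPlan:
    """Enumerate the omitted-seed configurations (deterministic per seed)."""
    symbols = list(seeds.symbols) if isinstance(seeds, SeedList) else list(seeds)
    central = graph_model.normalize_symbol(central)
    if central not in symbols:
        raise ValueError(f"central gene {central} is not in the seed list")
    if not (1 <= k_max <= len(symbols)):
        raise ValueError(f"k_max must be in [1, {len(symbols)}], got {k_max}")

    rng = np.random.default_rng(rng_seed)
    others = [s for s in symbols if s != central]
    groups: dict[int, list[frozenset[str]]] = {}
    groups[1] = [frozenset({s}) for s in symbols]
    if k_max >= 2:
        groups[2] = [frozenset({central, s}) for s in others]
    for k in range(3, k_max + 1):
        draws = []
        for _ in range(draws_per_k):
            pick = rng.choice(len(others), size=k - 1, replace=False)
            draws.append(frozenset({central} | {others[i] for i in sorted(pick)}))
        groups[k] = draws
    return OmissionPlan(groups, central, draws_per_k, rng_seed)


@dataclass
class TestNetworkResult:
    """Outcome of rebuilding the network with some seeds omitted."""

    k: int
    omitted: frozenset[str]
    top_bc_node: str
    top_m: set[str]
    accuracy: float
    giant_size: int


def run_test_network(
    omitted: Sequence[str] | frozenset[str],
    seeds: SeedList | Sequence[str],
    interactions: InteractionTable,
    reference_backbone: Sequence[str],
    m: int | None = None,
    min_score: float = 400.0,
    k: int | None = None,
) -> TestNetworkResult:
    """Rebuild the extended network without ``omitted`` seeds and score it.

    The top-M set is truncated to exactly M by rank (BC descending, ties
    by symbol) so the accuracy denominator is fixed; if the test network's
    giant component is smaller than M the accuracy is computed over the
    available nodes.
    """
    symbols = list(seeds.symbols) if isinstance(seeds, SeedList) else list(seeds)
    omitted = frozenset(omitted)
    remaining = [s for s in symbols if s not in omitted]
    if not remaining:
        raise ValueError("omitting every seed leaves nothing to build from")
    ref = set(reference_backbone)
    m = len(ref) if m is None else m

    net = graph_model.build_extended_network(remaining, interactions,
                                             min_score=min_score)
    giant = graph_model.giant_component(net)
    bc = centrality.betweenness(giant)
    ranked = sorted(bc, key=lambda n: (-bc[n], n))
    top_m = ranked[:m]
    acc = len(set(top_m) & ref) / len(top_m)
    return TestNetworkResult(
        k=len(omitted) if k is None else k,
        omitted=omitted,
        top_bc_node=ranked[0],
        top_m=set(top_m),
        accuracy=acc,
        giant_size=giant.number_of_nodes(),
    )


@dataclass
class RobustnessSummary:
    """Per-k and overall largest-BC frequencies and backbone accuracy."""

    per_k: pd.DataFrame          # rows: k; columns: per-node freq, accuracy, n
    candidate_nodes: list[str]   # every node that topped BC at least once
    overall_accuracy: float      # unweighted mean of per-k mean accuracies
    weighted_accuracy: float     # network-weighted mean, for comparison
    total_networks: int
    frequency_totals: dict[str, int] = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        """Per-k rows plus a Summary row (the published table layout)."""
        df = self.per_k.copy()
        summary = {"k": "Summary",
                   **{n: self.frequency_totals[n] for n in self.candidate_nodes},
                   "accuracy": self.overall_accuracy,
                   "n_networks": self.total_networks}
        return pd.concat([df, pd.DataFrame([summary])], ignore_index=True)


def summarize_groups(
    group_rows: Sequence[tuple[int, Mapping[str, int], float, int]],
) -> RobustnessSummary:
    """Aggregate per-k group rows (k, top-BC frequency per node, mean
    accuracy, group size) into the overall summary.

    The overall accuracy is the *unweighted* mean of the per-k mean
    accuracies; the network-weighted mean is also computed and exposed.
    Per-node frequency totals are column sums.
    """
    if not group_rows:
        raise ValueError("no groups to summarize")
    nodes = sorted({n for _, freq, _, _ in group_rows for n in freq})
    rows = []
    for k, freq, acc, n_nets in group_rows:
        if sum(freq.values()) != n_nets:
            raise ValueError(
                f"group k={k}: frequencies sum to {sum(freq.values())} "
                f"but group size is {n_nets}"
            )
        rows.append({"k": k, **{n: freq.get(n, 0) for n in nodes},
                     "accuracy": acc, "n_networks": n_nets})
    per_k = pd.DataFrame(rows, columns=["k", *nodes, "accuracy", "n_networks"])
    totals = {n: int(per_k[n].sum()) for n in nodes}
    total_nets = int(per_k["n_networks"].sum())
    overall = float(per_k["accuracy"].mean())
    weighted = float((per_k["accuracy"] * per_k["n_networks"]).sum() / total_nets)
    return RobustnessSummary(per_k, nodes, overall, weighted, total_nets, totals)


def summarize(results: Sequence[TestNetworkResult],
              plan: OmissionPlan) -> RobustnessSummary:
    """Summarize one result per plan configuration into the per-k table."""
    expected = plan.n_configurations
    if len(results) != expected:
        raise ValueError(
            f"expected {expected} results (one per plan configuration), "
            f"got {len(results)}"
        )
    group_rows = []
    for k in sorted(plan.groups):
        group = [r for r in results if r.k == k]
        if len(group) != len(plan.groups[k]):
            raise ValueError(f"group k={k}: missing results")
        freq: dict[str, int] = {}
        for r in group:
            freq[r.top_bc_node] = freq.get(r.top_bc_node, 0) + 1
        acc = float(np.mean([r.accuracy for r in group]))
        group_rows.append((k, freq, acc, len(group)))
    return summarize_groups(group_rows)


def run_protocol(
    seeds: SeedList | Sequence[str],
    interactions: InteractionTable,
    reference_backbone: Sequence[str],
    central: str,
    k_max: int = 7,
    draws_per_k: int = 30,
    rng_seed: int = 0,
    min_score: float = 400.0,
) -> tuple[OmissionPlan, list[TestNetworkResult], RobustnessSummary]:
    """Full protocol: plan, run every test network, summarize."""
    plan = build_omission_plan(seeds, central, k_max=k_max,
                               draws_per_k=draws_per_k, rng_seed=rng_seed)
    results = [
        run_test_network(omitted, seeds, interactions, reference_backbone,
                         min_score=min_score, k=k)
        for k, omitted in plan
    ]
    return plan, results, summarize(results, plan)
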