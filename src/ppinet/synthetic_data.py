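"""Synthetic STRING-like interactomes with known ground truth.

Real disease-gene PPI studies start from a database snapshot that cannot
be redistributed and drifts between versions, so every pipeline stage here
is exercised against generated interactomes whose answers are known by
construction:

* a scale-free background (preferential attachment), mimicking the
  heavy-tailed degree distribution of human PPI networks;
* a designated *bridge* node adjacent to every member of a handful of
  dense modules (cliques) that touch nothing else, making the bridge the
  unique cut vertex between all module mass and the background — it is
  therefore guaranteed the maximal betweenness once the modules are large
  enough, and has high degree too (the planted analogue of a central
  protein such as NOS3);
* confidence scores such that a known fraction of edges falls below the
  default inclusion threshold (these sub-threshold "noise" edges are
  random pairs, so the planted topology is exactly recoverable at the
  default threshold);
* small detached two-node components ("satellites"), each carrying one
  seed, reproducing the seeds that fall outside the giant component.

Seed lists are sampled so that every module carries at least two seeds
(the extended network then always contains the full modules and the
bridge) and the bridge itself is, by default, *not* a seed: it enters the
network only as a neighbour, reproducing the phenomenon of a non-seed
protein dominating the centrality ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .graph_model import InteractionTable
from .io_formats import SeedList


@dataclass
class SyntheticConfig:
    """Generator parameters.

    Defaults emulate the shape of the published study scaled to its
    interactome: ~500 background proteins, 69 seed genes, one planted
    bridge, two 2-node satellites, 20% of edges below the 400 score
    threshold.
    """

    n_background: int = 500
    attachment_edges: int = 2
    n_modules: int = 4
    module_size: int = 25
    bridge_node: str = "BRG1"
    bridge_anchors: int = 8          # background hubs the bridge attaches to
    n_satellites: int = 2
    n_seeds: int = 69
    seed_in_giant_fraction: float = 67 / 69
    bridge_is_seed: bool = False
    min_seeds_per_module: int = 2
    noise_edge_ratio: float = 0.25   # noise edges per structural edge (-> 20% of total)
    score_threshold: float = 400.0   # scores straddle this value
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_background", "attachment_edges", "module_size",
                     "n_seeds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_modules < 0 or self.n_satellites < 0:
            raise ValueError("n_modules and n_satellites must be non-negative")
        if not (0 < self.seed_in_giant_fraction <= 1):
            raise ValueError("seed_in_giant_fraction must be in (0, 1]")


@dataclass
class GroundTruth:
    """What the generator planted."""

    bridge_node: str
    background: set[str]
    background_degree: dict[str, int] = field(default_factory=dict)
    modules: list[set[str]] = field(default_factory=list)
    satellites: list[set[str]] = field(default_factory=list)
    satellite_seeds: list[str] = field(default_factory=list)
    structural_edges: int = 0
    noise_edges: int = 0

    @property
    def giant_members(self) -> set[str]:
        """Designed giant region: background + modules + bridge."""
        out = set(self.background)
        for m in self.modules:
            out |= m
        if self.modules or self.background:
            out.add(self.bridge_node)
        return out


def _name(prefix: str, i: int) -> str:
    return f"{prefix}{i:04d}"


def generate_interactome(cfg: SyntheticConfig) -> tuple[InteractionTable, GroundTruth]:
    """Generate the interaction table and its ground truth.

    Structural edges (background, modules, bridge attachments, satellites)
    receive scores uniform on [threshold, 1000]; noise edges — random
    non-structural pairs, ``noise_edge_ratio`` per structural edge —
    receive scores uniform on [100, threshold). Filtering at the default
    threshold therefore recovers the planted topology exactly; below it,
    noise edges may break the bridge-cut guarantee.

    A verification pass asserts the planted cut property: removing the
    bridge disconnects every module from the background.
    """
    if cfg.n_modules > 0 and cfg.module_size < 2:
        raise ValueError("modules need at least 2 nodes to be wirable")
    if cfg.attachment_edges >= cfg.n_background:
        raise ValueError("attachment_edges must be below n_background")
    rng = np.random.default_rng(cfg.rng_seed)

    bg = [_name("BKG", i) for i in range(cfg.n_background)]
    g = nx.barabasi_albert_graph(cfg.n_background, cfg.attachment_edges,
                                 seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, {i: bg[i] for i in range(cfg.n_background)})

    truth = GroundTruth(bridge_node=cfg.bridge_node, background=set(bg),
                        background_degree={n: int(d) for n, d in g.degree()})

    if cfg.n_modules > 0:
        for mi in range(cfg.n_modules):
            members = {_name(f"MOD{chr(65 + mi)}", j) for j in range(cfg.module_size)}
            truth.modules.append(members)
            for a in members:
                g.add_edge(cfg.bridge_node, a)  # bridge adjacent to whole module
            for a in sorted(members):
                for b in sorted(members):
                    if a < b:
                        g.add_edge(a, b)        # module is a clique
        # anchor the bridge on the largest background hubs: hubs are almost
        # surely adjacent to some seed, so the module-bridge block stays
        # attached to the background under any seed-omission pattern
        hubs = sorted(bg, key=lambda n: (-g.degree(n), n))
        for a in hubs[:min(cfg.bridge_anchors, cfg.n_background)]:
            g.add_edge(cfg.bridge_node, a)

    for si in range(cfg.n_satellites):
        a, b = _name(f"SAT{chr(65 + si)}", 0), _name(f"SAT{chr(65 + si)}", 1)
        truth.satellites.append({a, b})
        truth.satellite_seeds.append(a)
        g.add_edge(a, b)

    # cut-property verification: without the bridge, no module reaches the background
    if cfg.n_modules > 0:
        probe = g.copy()
        probe.remove_node(cfg.bridge_node)
        anchor = bg[0]
        for members in truth.modules:
            for m in members:
                if nx.has_path(probe, m, anchor):
                    raise RuntimeError(
                        "planted cut property violated: module node "
                        f"{m} reaches the background without the bridge"
                    )

    structural = sorted(tuple(sorted(e)) for e in g.edges)
    truth.structural_edges = len(structural)
    lo, hi = cfg.score_threshold, 1000.0
    rows = [(a, b, float(np.round(s, 1)))
            for (a, b), s in zip(structural,
                                 rng.uniform(lo, hi, size=len(structural)))]

    n_noise = int(round(cfg.noise_edge_ratio * len(structural)))
    existing = set(structural)
    all_nodes = sorted(g.nodes)
    noise: list[tuple[str, str]] = []
    guard = 0
    while len(noise) < n_noise and guard < 100 * n_noise + 100:
        guard += 1
        i, j = rng.integers(len(all_nodes), size=2)
        a, b = all_nodes[int(i)], all_nodes[int(j)]
        if a == b:
            continue
        key = (a, b) if a < b else (b, a)
        if key in existing:
            continue
        existing.add(key)
        noise.append(key)
    truth.noise_edges = len(noise)
    rows += [(a, b, float(np.round(s, 1)))
             for (a, b), s in zip(noise,
                                  rng.uniform(100.0, cfg.score_threshold - 1,
                                              size=len(noise)))]

    return InteractionTable(sorted(rows)).cleaned(), truth


def generate_seed_list(cfg: SyntheticConfig, truth: GroundTruth) -> SeedList:
    """Sample the seed gene list against the planted ground truth.

    ``round(seed_in_giant_fraction * n_seeds)`` seeds come from the giant
    region (with at least ``min_seeds_per_module`` in every module and the
    bridge excluded unless ``bridge_is_seed``); the remainder are the
    designated satellite seeds, one per satellite.
    """
    rng = np.random.default_rng(cfg.rng_seed + 1)
    n_giant = int(round(cfg.seed_in_giant_fraction * cfg.n_seeds))
    n_sat = cfg.n_seeds - n_giant
    if n_sat > len(truth.satellite_seeds):
        raise ValueError(
            f"{n_sat} satellite seeds requested but only "
            f"{len(truth.satellite_seeds)} satellites exist"
        )

    pool = sorted(truth.giant_members)
    if not cfg.bridge_is_seed and truth.bridge_node in pool:
        pool.remove(truth.bridge_node)
    if n_giant > len(pool):
        raise ValueError("n_seeds exceeds the available giant-region nodes")

    chosen: list[str] = []
    for members in truth.modules:
        take = min(cfg.min_seeds_per_module, len(members))
        pick = rng.choice(sorted(members), size=take, replace=False)
        chosen += [str(p) for p in pick]
    chosen = chosen[:n_giant]
    rest_pool = [p for p in pool if p not in set(chosen)]
    n_rest = n_giant - len(chosen)
    if n_rest > 0:
        # degree-weighted sampling: disease seeds are preferentially
        # well-connected, and well-connected seeds keep the extended
        # network from shedding peripheral fragments
        w = np.array([truth.background_degree.get(p, 1) for p in rest_pool],
                     dtype=float)
        pick = rng.choice(rest_pool, size=n_rest, replace=False, p=w / w.sum())
        chosen += [str(p) for p in pick]
    chosen += truth.satellite_seeds[:n_sat]
    return SeedList([(s, "synthetic seed") for s in sorted(chosen)])
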