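"""End-to-end orchestration: config, run directory, manifest, reports.

A run executes the full analysis chain — extended-network construction,
component decomposition, global statistics, per-node centralities,
high-BC backbone and key-node classification, the all-shortest-paths seed
subnetwork, and (optionally) the seed-omission robustness protocol — and
writes every result as a TSV table plus Pajek graph files, together with
a JSON manifest recording the exact configuration and software version.
Re-running with a manifest's config reproduces byte-identical tables:
every randomized stage draws from a named sub-seed derived from the run's
``rng_seed``, and no output embeds a timestamp.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__, centrality, graph_model, io_formats, robustness, subnetworks
from .graph_model import PpinetError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    Defaults reproduce the published protocol shape: STRING
    medium-confidence score cutoff 400, top-5% backbone, omission depths
    1..7 with 30 random draws per depth.
    """

    seeds: str = ""
    interactions: str = ""
    out_dir: str = "ppinet_run"
    min_score: float = 400.0
    fraction: float = 0.05
    central_gene: str | None = None   # default: highest-BC seed in the giant
    k_max: int = 7
    draws_per_k: int = 30
    rng_seed: int = 0
    keep_missing_seeds: bool = False
    emit_pajek: bool = True
    run_robustness: bool = True
    score_column: int = 2
    score_scale: float = 1000.0
    alias: str | None = None
    path_cap: int = 100_000

    def __post_init__(self) -> None:
        if not (0 < self.fraction <= 1):
            raise ValueError(f"fraction must be in (0, 1], got {self.fraction}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def sub_seed(self, stage: str) -> int:
        """Named sub-seed so each randomized stage is independently
        reproducible. Stable across processes (not hash()-based)."""
        h = 2166136261
        for byte in f"{self.rng_seed}:{stage}".encode():
            h = ((h ^ byte) * 16777619) % 2**31
        return h


@dataclass
class RunResult:
    """In-memory bundle of everything a run computed."""

    config: RunConfig
    extended: Any
    decomposition: graph_model.ComponentDecomposition
    giant: Any
    giant_stats: centrality.NetworkStats
    degree: dict[str, int]
    bc: dict[str, float]
    cc: dict[str, float]
    backbone: subnetworks.BackboneResult
    backbone_stats: centrality.NetworkStats | None
    key_nodes: subnetworks.KeyNodeClassification
    seed_subnetwork: subnetworks.SeedSubnetwork | None
    robustness_summary: robustness.RobustnessSummary | None = None
    robustness_results: list[robustness.TestNetworkResult] = field(default_factory=list)
    central_gene: str | None = None


def analyze(seed_list: io_formats.SeedList,
            interactions: graph_model.InteractionTable,
            cfg: RunConfig) -> RunResult:
    """Run the analysis chain on in-memory inputs."""
    stage = "build_extended_network"
    try:
        extended = graph_model.build_extended_network(
            seed_list.symbols, interactions,
            min_score=cfg.min_score, keep_missing_seeds=cfg.keep_missing_seeds)
        stage = "decompose_components"
        decomp = graph_model.decompose_components(extended)
        giant = graph_model.induced_subgraph(extended, decomp.giant)

        stage = "centrality"
        deg = centrality.degree(giant)
        bc = centrality.betweenness(giant)
        cc = centrality.closeness(giant)
        stats = centrality.global_stats(giant)

        stage = "backbone"
        backbone = subnetworks.extract_backbone(giant, bc, cfg.fraction)
        bb_stats = None
        try:
            bb_stats = centrality.global_stats(backbone.backbone_net)
        except PpinetError:
            logger.info("backbone is disconnected; global stats omitted")
        key = subnetworks.classify_key_nodes(deg, bc, giant.number_of_nodes(),
                                             cfg.fraction)

        stage = "seed_subnetwork"
        giant_seeds = sorted(graph_model.seeds_of(giant))
        subnet = None
        if len(giant_seeds) >= 2:
            subnet = subnetworks.seed_shortest_path_subnetwork(
                giant, giant_seeds, path_cap=cfg.path_cap)
        else:
            logger.warning("fewer than 2 seeds in the giant component; "
                           "seed subnetwork skipped")

        result = RunResult(cfg, extended, decomp, giant, stats, deg, bc, cc,
                           backbone, bb_stats, key, subnet)

        stage = "robustness"
        if cfg.run_robustness:
            central = cfg.central_gene
            if central is None:
                ranked_seeds = sorted(giant_seeds, key=lambda n: (-bc[n], n))
                central = ranked_seeds[0]
                logger.info("central gene defaulted to highest-BC seed: %s", central)
            _, results, summary = robustness.run_protocol(
                seed_list, interactions, backbone.nodes, central,
                k_max=cfg.k_max, draws_per_k=cfg.draws_per_k,
                rng_seed=cfg.sub_seed("omission_plan"),
                min_score=cfg.min_score)
            result.robustness_results = results
            result.robustness_summary = summary
            result.central_gene = central
        return result
    except Exception as exc:
        raise PpinetError(f"stage {stage!r} failed: {exc}") from exc


def write_reports(res: RunResult, out_dir: str | Path) -> dict[str, Path]:
    """Write all report tables, Pajek files and the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = res.config
    written: dict[str, Path] = {}

    stats = {"giant_network": res.giant_stats}
    if res.backbone_stats is not None:
        stats["backbone_network"] = res.backbone_stats
    tables: dict[str, pd.DataFrame] = {
        "network_stats": io_formats.stats_frame(stats),
        "centrality": io_formats.centrality_frame(
            res.degree, res.bc, res.cc, graph_model.seeds_of(res.giant)),
        "backbone_members": pd.DataFrame(
            [{"rank": i + 1, "node": n, "bc": v, "cc": res.cc[n]}
             for i, (n, v) in enumerate(res.backbone.members)]),
        "key_nodes": pd.DataFrame(
            [{"node": n, "class": res.key_nodes.labels[n],
              "degree": res.degree[n], "bc": res.bc[n]}
             for n in sorted(res.key_nodes.labels,
                             key=lambda x: (-res.bc[x], x))
             if res.key_nodes.labels[n] != "nonhub-nonbottleneck"]),
        "components": pd.DataFrame(
            [{"component": i + 1, "size": len(c),
              "members": ";".join(sorted(c)) if len(c) <= 30 else
              f"{len(c)} nodes (giant)"}
             for i, c in enumerate(res.decomposition.components)]),
    }
    if res.seed_subnetwork is not None:
        tables["subnetwork_bc"] = pd.DataFrame(
            [{"rank": i + 1, "node": n, "bc": v,
              "is_seed": n in graph_model.seeds_of(res.seed_subnetwork.net)}
             for i, (n, v) in enumerate(res.seed_subnetwork.bc_ranking)])
    if res.robustness_summary is not None:
        tables["robustness_summary"] = res.robustness_summary.as_frame()
        tables["robustness_detail"] = pd.DataFrame(
            [{"k": r.k, "omitted": ";".join(sorted(r.omitted)),
              "top_bc_node": r.top_bc_node, "accuracy": r.accuracy,
              "giant_size": r.giant_size}
             for r in res.robustness_results])
    for p in io_formats.write_results_tables(tables, f"{out}/"):
        written[p.stem] = p

    if cfg.emit_pajek:
        io_formats.write_pajek(res.extended, out / "extended_network.net")
        io_formats.write_pajek(res.giant, out / "giant_network.net")
        io_formats.write_pajek(res.backbone.backbone_net, out / "backbone_network.net")
        if res.seed_subnetwork is not None:
            io_formats.write_pajek(res.seed_subnetwork.net, out / "seed_subnetwork.net")

    manifest = {
        "ppinet_version": __version__,
        "config": dataclasses.asdict(cfg),
        "central_gene": res.central_gene,
        "n_extended": res.extended.number_of_nodes(),
        "component_sizes": res.decomposition.sizes,
        "backbone_cutoff": res.backbone.cutoff,
        "reports": sorted(written),
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written["manifest"] = mpath
    return written


def run_full_analysis(cfg: RunConfig) -> RunResult:
    """Read inputs per ``cfg``, run the analysis, write all reports."""
    for label, p in [("seed list", cfg.seeds), ("interaction table", cfg.interactions)]:
        if not p or not Path(p).exists():
            raise PpinetError(f"{label} not found: {p!r}")
    seed_list = io_formats.read_seed_list(cfg.seeds)
    alias = io_formats.read_alias(cfg.alias) if cfg.alias else None
    table = io_formats.read_interactions(
        cfg.interactions, score_column=cfg.score_column,
        scale=cfg.score_scale, alias=alias)
    res = analyze(seed_list, table, cfg)
    write_reports(res, cfg.out_dir)
    logger.info("run complete: %d nodes in giant, backbone cutoff %d",
                res.giant.number_of_nodes(), res.backbone.cutoff)
    return res
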