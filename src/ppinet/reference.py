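"""Shipped reference data for the essential-hypertension study.

Two kinds of fixture travel with the package:

* the 69-gene seed list curated from the hypertension literature — the
  standard input for a real analysis run;
* the study's published per-group robustness results and bookkeeping
  counts. The underlying interactome (a historical STRING v9.0 snapshot)
  is not redistributable, so these serve as *inputs* to the protocol
  arithmetic (aggregation, cutoff and plan-size rules), not as values the
  package recomputes from raw data.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .io_formats import SeedList, read_seed_list
from .robustness import RobustnessSummary, summarize_groups

_DATA = resources.files("ppinet") / "data"


def seed_gene_list() -> SeedList:
    """The 69 essential-hypertension seed genes (ACE2 ... WNK4)."""
    with resources.as_file(_DATA / "eh_seed_genes.tsv") as p:
        return read_seed_list(p)


def published_reference() -> dict:
    """Published network-level counts and parameters of the study."""
    return json.loads((_DATA / "eh_reference.json").read_text())


def robustness_group_table() -> pd.DataFrame:
    """Published per-k test-network results: largest-BC frequency per
    candidate node, group mean backbone accuracy, group size."""
    with resources.as_file(_DATA / "eh_robustness_groups.tsv") as p:
        return pd.read_csv(p, sep="\t")


def published_robustness_summary() -> RobustnessSummary:
    """Aggregate the published per-k rows through the package's own
    summary arithmetic (frequency column sums; unweighted group-mean
    accuracy)."""
    df = robustness_group_table()
    nodes = [c for c in df.columns if c not in {"k", "accuracy", "n_networks"}]
    rows = [
        (int(r["k"]), {n: int(r[n]) for n in nodes},
         float(r["accuracy"]), int(r["n_networks"]))
        for _, r in df.iterrows()
    ]
    return summarize_groups(rows)
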