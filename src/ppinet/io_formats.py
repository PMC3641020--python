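"""Readers and writers: seed lists, STRING-style interaction tables,
Pajek .net graphs, and delimited result tables.

Interaction tables are STRING exports in spirit: delimited text with two
node identifier columns and a confidence score column. Both the 0-1000
combined-score scale and a 0-1 scale are accepted; scores are canonicalized
to 0-1000 internally. A two-column dialect (no score) is read as
unweighted, every row at the scale maximum.

The Pajek dialect written here is the minimal undirected one: a
``*Vertices N`` header, 1-based vertex ids with quoted labels, and a
``*Edges`` section of id pairs. ``*Arcs`` sections are rejected on read
(the networks here are undirected).
"""

from __future__ import annotations

import logging
import shlex
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .graph_model import InteractionTable, PpinetError, normalize_symbol, seeds_of

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.5f"  # output precision for all result tables


class FormatError(PpinetError):
    """Malformed input file."""


@dataclass
class SeedList:
    """Ordered, unique seed gene symbols with optional descriptions.

    Order is significant: the seed-omission protocol indexes into it.
    """

    entries: list[tuple[str, str]] = field(default_factory=list)

    @property
    def symbols(self) -> list[str]:
        return [s for s, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, symbol: str) -> bool:
        return symbol in set(self.symbols)


def read_seed_list(path: str | Path) -> SeedList:
    """Read a seed list: one symbol per line, or TSV with symbol first and
    a free-text description second. ``#``-prefixed lines and a
    symbol/description header row are skipped; duplicates are collapsed
    with a warning; symbols are case-normalized.
    """
    path = Path(path)
    entries: list[tuple[str, str]] = []
    seen: set[str] = set()
    dupes: list[str] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        token = parts[0].strip()
        if lineno == 1 and token.lower() in {"symbol", "gene", "id"}:
            continue
        try:
            sym = normalize_symbol(token)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        desc = parts[1].strip() if len(parts) > 1 else ""
        if sym in seen:
            dupes.append(sym)
            continue
        seen.add(sym)
        entries.append((sym, desc))
    if dupes:
        logger.warning("%s: %d duplicate seed symbol(s) collapsed: %s",
                       path, len(dupes), ", ".join(sorted(set(dupes))))
    if not entries:
        raise FormatError(f"{path}: seed list is empty")
    return SeedList(entries)


def write_seed_list(seeds: SeedList, path: str | Path) -> None:
    lines = ["symbol\tdescription"]
    lines += [f"{s}\t{d}" for s, d in seeds.entries]
    Path(path).write_text("\n".join(lines) + "\n")


def read_interactions(
    path: str | Path,
    score_column: int | str = 2,
    scale: float = 1000.0,
    sep: str | None = None,
    alias: Mapping[str, str] | None = None,
) -> InteractionTable:
    """Read a STRING-style interaction table and clean it.

    Parameters
    ----------
    score_column
        Positional index (0-based) or header name of the confidence column.
        Ignored for the two-column unweighted dialect, where every row gets
        the scale maximum.
    scale
        Maximum of the score scale in the file (1000 for STRING
        combined_score, 1 for a probability dialect). Scores are rescaled
        to 0-1000 internally.
    alias
        Optional mapping applied to table identifiers before cleaning
        (e.g. protein ids back to the seed gene symbols).
    """
    path = Path(path)
    if not path.read_text().strip():
        raise FormatError(f"{path}: interaction table is empty")
    try:
        df = pd.read_csv(path, sep=sep, engine="python", comment="#",
                         header=None, dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: interaction table is empty") from None

    # A header row of non-numeric score values is tolerated and dropped.
    header: list[str] | None = None
    first = [str(v) for v in df.iloc[0]]
    if len(df.columns) >= 3 and not _is_number(first[-1]):
        header = [h.strip() for h in first]
        df = df.iloc[1:].reset_index(drop=True)
        if df.empty:
            raise FormatError(f"{path}: interaction table has a header but no rows")

    ncol = len(df.columns)
    if ncol < 2:
        raise FormatError(f"{path}: expected >= 2 columns, found {ncol}")

    if ncol == 2:
        score_idx = None
    elif isinstance(score_column, str):
        if header is None or score_column not in header:
            raise FormatError(f"{path}: unknown score column {score_column!r}")
        score_idx = header.index(score_column)
    else:
        if not (0 <= int(score_column) < ncol):
            raise FormatError(f"{path}: unknown score column {score_column!r}")
        score_idx = int(score_column)

    rows: list[tuple[str, str, float]] = []
    offset = 2 if header is not None else 1
    for i, rec in enumerate(df.itertuples(index=False), start=offset):
        a, b = str(rec[0]), str(rec[1])
        if alias:
            a = alias.get(a.strip().upper(), a)
            b = alias.get(b.strip().upper(), b)
        if score_idx is None:
            score = float(scale)
        else:
            raw = str(rec[score_idx])
            if not _is_number(raw):
                raise FormatError(f"{path}:{i}: unparseable score {raw!r}")
            score = float(raw)
        try:
            rows.append((normalize_symbol(a), normalize_symbol(b),
                         score * 1000.0 / scale))
        except ValueError as exc:
            raise FormatError(f"{path}:{i}: {exc}") from exc
    return InteractionTable(rows).cleaned()


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except (TypeError, ValueError):
        return False


def write_interactions(table: InteractionTable, path: str | Path) -> None:
    lines = [f"{a}\t{b}\t{s:g}" for a, b, s in table.rows]
    Path(path).write_text("\n".join(lines) + "\n")


def read_alias(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping table identifiers to seed symbols."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected two columns")
        out[parts[0].strip().upper()] = parts[1].strip().upper()
    return out


# ---------------------------------------------------------------------------
# Pajek .net
# ---------------------------------------------------------------------------

def write_pajek(net: nx.Graph, path: str | Path) -> None:
    """Write ``net`` in the minimal undirected Pajek .net dialect."""
    if net.number_of_nodes() == 0:
        raise PpinetError("refusing to write an empty network")
    nodes = sorted(net.nodes)
    index = {n: i + 1 for i, n in enumerate(nodes)}
    lines = [f"*Vertices {len(nodes)}"]
    lines += [f'{index[n]} "{n}"' for n in nodes]
    lines.append("*Edges")
    for a, b in sorted(tuple(sorted(e)) for e in net.edges):
        lines.append(f"{index[a]} {index[b]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pajek(path: str | Path, seeds: Iterable[str] = ()) -> nx.Graph:
    """Read a Pajek .net file written by :func:`write_pajek`.

    ``*Arcs`` sections are rejected: the networks here are undirected.
    Optional ``seeds`` re-establish seed flags (labels not present are
    ignored).
    """
    path = Path(path)
    g = nx.Graph()
    labels: dict[int, str] = {}
    section = None
    n_expected = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        low = line.lower()
        if low.startswith("*"):
            if low.startswith("*vertices"):
                parts = line.split()
                if len(parts) < 2 or not parts[1].isdigit():
                    raise FormatError(f"{path}:{lineno}: malformed *Vertices header")
                n_expected = int(parts[1])
                section = "vertices"
            elif low.startswith("*edges"):
                section = "edges"
            elif low.startswith("*arcs"):
                raise FormatError(
                    f"{path}:{lineno}: *Arcs section found; this reader only "
                    "accepts undirected *Edges networks"
                )
            else:
                raise FormatError(f"{path}:{lineno}: unknown section {line!r}")
            continue
        if section == "vertices":
            try:
                parts = shlex.split(line)
                vid = int(parts[0])
                label = parts[1] if len(parts) > 1 else str(vid)
            except (ValueError, IndexError):
                raise FormatError(f"{path}:{lineno}: malformed vertex line {line!r}")
            labels[vid] = label
            g.add_node(label, seed=False)
        elif section == "edges":
            parts = line.split()
            try:
                a, b = int(parts[0]), int(parts[1])
            except (ValueError, IndexError):
                raise FormatError(f"{path}:{lineno}: malformed edge line {line!r}")
            if a not in labels or b not in labels:
                raise FormatError(f"{path}:{lineno}: edge references unknown vertex id")
            if a != b:
                g.add_edge(labels[a], labels[b])
        else:
            raise FormatError(f"{path}:{lineno}: data line before any section header")
    if n_expected is not None and len(labels) != n_expected:
        raise FormatError(
            f"{path}: *Vertices announced {n_expected} vertices, found {len(labels)}"
        )
    for s in seeds:
        if s in g:
            g.nodes[s]["seed"] = True
    return g


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with 5-decimal floats."""
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def centrality_frame(degree: Mapping[str, int], bc: Mapping[str, float],
                     cc: Mapping[str, float],
                     seeds: Iterable[str] = ()) -> pd.DataFrame:
    """Per-node centrality table sorted by BC descending (ties by symbol)."""
    seeds = set(seeds)
    rows = [
        {"node": n, "degree": degree[n], "bc": bc[n], "cc": cc[n],
         "is_seed": n in seeds}
        for n in degree
    ]
    rows.sort(key=lambda r: (-r["bc"], r["node"]))
    return pd.DataFrame(rows, columns=["node", "degree", "bc", "cc", "is_seed"])


def stats_frame(stats_by_name: Mapping[str, "NetworkStats"]) -> pd.DataFrame:
    """Global-measurements table: one column per network, rows N, E, <k>,
    D, mspl (the layout of the published summary table)."""
    from .centrality import NetworkStats  # noqa: F401  (typing only)

    rows = []
    for sym, attr, desc in [
        ("N", "n", "number of nodes"),
        ("E", "e", "number of edges"),
        ("<k>", "avg_degree", "average degree"),
        ("D", "diameter", "diameter"),
        ("mspl", "mspl", "mean shortest path length"),
    ]:
        row = {"symbol": sym, "description": desc}
        for name, st in stats_by_name.items():
            row[name] = getattr(st, attr)
        rows.append(row)
    return pd.DataFrame(rows)


def write_results_tables(tables: Mapping[str, pd.DataFrame],
                         path_prefix: str | Path) -> list[Path]:
    """Write one TSV per named report, ``<prefix><name>.tsv`` (a prefix
    ending in a path separator writes into that directory)."""
    written = []
    for name, df in tables.items():
        p = Path(f"{path_prefix}{name}.tsv")
        p.parent.mkdir(parents=True, exist_ok=True)
        write_table(df, p)
        written.append(p)
    return written


def network_to_edge_frame(net: nx.Graph) -> pd.DataFrame:
    seeds = seeds_of(net)
    rows = [{"id_a": a, "id_b": b, "a_is_seed": a in seeds, "b_is_seed": b in seeds}
            for a, b in sorted(tuple(sorted(e)) for e in net.edges)]
    return pd.DataFrame(rows, columns=["id_a", "id_b", "a_is_seed", "b_is_seed"])
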