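"""Windowed co-authorship network construction.

Institutions are nodes; two institutions are tied in a window when they
co-appear on at least one publication dated within that window. Networks
are simple (no self-loops, no parallel edges) and analyzed unweighted;
the number of joint publications is kept as an edge attribute.

Inclusion rules for a window (y, y + L - 1), default L = 2 with one-year
steps so a 2008-2019 span yields eleven overlapping networks:

* an institution enters the node set of every window from its first
  publication onward (cumulative entry), whether or not it publishes in
  the window — isolates are retained;
* except institutions active in exactly one calendar year, which appear
  only in the windows containing that year.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import networkx as nx

from .errors import ConfigurationError
from .records import Corpus
from .resolve import Institution


@dataclass
class WindowNetwork:
    """Undirected simple institution graph for one publication window."""

    window: tuple[int, int]
    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def label(self) -> str:
        return f"{self.window[0]}-{self.window[1]}"

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class NetworkSeries:
    """Ordered sequence of overlapping window networks."""

    windows: list[WindowNetwork]

    def __iter__(self) -> Iterator[WindowNetwork]:
        return iter(self.windows)

    def __len__(self) -> int:
        return len(self.windows)

    def __getitem__(self, i) -> WindowNetwork:
        return self.windows[i]

    @property
    def by_label(self) -> dict[str, WindowNetwork]:
        return {w.label: w for w in self.windows}


def active_years(corpus: Corpus) -> dict[str, set[int]]:
    """canonical_id -> set of calendar years with >= 1 publication."""
    out: dict[str, set[int]] = {}
    for rec in corpus:
        for cid in rec.institution_ids():
            out.setdefault(cid, set()).add(rec.year)
    return out


def single_year_institutions(corpus: Corpus) -> set[str]:
    """Institutions whose publications all fall in a single calendar year."""
    return {cid for cid, ys in active_years(corpus).items() if len(ys) == 1}


def build_series(
    corpus: Corpus,
    registry: Mapping[str, Institution],
    first_year: int,
    last_year: int,
    window_len: int = 2,
    step: int = 1,
) -> NetworkSeries:
    """Build the sequence of window networks under the inclusion rules.

    The corpus must already be filtered (target region, large teams) and
    entity-resolved; ``registry`` supplies node attributes (country, region
    flag, sector). Edge weight = number of joint publications in the window;
    repeated mentions of one institution on one paper add no self-loop and
    no weight.
    """
    if window_len < 1 or step < 1:
        raise ConfigurationError("window_len and step must be >= 1")
    if last_year < first_year + window_len - 1:
        raise ConfigurationError(
            f"span [{first_year}, {last_year}] shorter than one {window_len}-year window"
        )
    years_of = active_years(corpus)
    singles = {cid for cid, ys in years_of.items() if len(ys) == 1}
    first_pub = {cid: min(ys) for cid, ys in years_of.items()}

    by_year: dict[int, list] = {}
    for rec in corpus:
        by_year.setdefault(rec.year, []).append(rec)

    series = []
    for start in range(first_year, last_year - window_len + 2, step):
        end = start + window_len - 1
        g = nx.Graph()
        for cid, fy in first_pub.items():
            if fy > end:
                continue
            if cid in singles and not (start <= min(years_of[cid]) <= end):
                continue
            inst = registry.get(cid)
            g.add_node(
                cid,
                is_african=inst.is_african if inst else False,
                sector=inst.sector if inst else "unknown",
                country=inst.country if inst else "??",
                name=inst.canonical_name if inst else cid,
            )
        for year in range(start, end + 1):
            for rec in by_year.get(year, []):
                members = sorted(rec.institution_ids())
                for i, u in enumerate(members):
                    for v in members[i + 1 :]:
                        if g.has_edge(u, v):
                            g[u][v]["weight"] += 1
                        else:
                            g.add_edge(u, v, weight=1)
        series.append(WindowNetwork(window=(start, end), graph=g))
    return NetworkSeries(windows=series)


def africa_subgraph(net: WindowNetwork) -> WindowNetwork:
    """Induced subgraph on the African nodes of a window network."""
    keep = [n for n, d in net.graph.nodes(data=True) if d.get("is_african")]
    return WindowNetwork(window=net.window, graph=net.graph.subgraph(keep).copy())


def write_graphml(net: WindowNetwork, path: str | Path) -> None:
    nx.write_graphml(net.graph, str(path))


def write_gexf(net: WindowNetwork, path: str | Path) -> None:
    nx.write_gexf(net.graph, str(path))


def write_edgelist_csv(net: WindowNetwork, path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "target", "weight"])
        for u, v, w in sorted(net.graph.edges(data="weight")):
            writer.writerow([u, v, w])


def write_series(series: NetworkSeries, outdir: str | Path, formats=("graphml", "gexf", "csv")) -> list[Path]:
    """Write every window under a predictable naming scheme (net_2008_2009.*)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for net in series:
        stem = f"net_{net.window[0]}_{net.window[1]}"
        if "graphml" in formats:
            p = outdir / f"{stem}.graphml"
            write_graphml(net, p)
            written.append(p)
        if "gexf" in formats:
            p = outdir / f"{stem}.gexf"
            write_gexf(net, p)
            written.append(p)
        if "csv" in formats:
            p = outdir / f"{stem}_edges.csv"
            write_edgelist_csv(net, p)
            written.append(p)
    return written
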