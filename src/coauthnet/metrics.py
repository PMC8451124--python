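"""Connectivity, group-mixing indices and centrality on window networks.

Mixing indices over the Africa / non-Africa partition of the nodes:

* E-I index = (E - I) / (E + I), with E the Africa<->non-Africa tie count
  and I the within-group tie count summed over both groups (Krackhardt &
  Stern). -1 means all ties internal, +1 all external.
* regionalization index R_A = (2 I_A - E_A) / (2 I_A + E_A), a group-level
  index for Africa: I_A counts Africa-Africa ties, E_A Africa-non-Africa
  ties. R_A = 0 when institutions in the region collaborate on average
  equally within and outside it; the average proportion of within-region
  ties of the region's institutions is (1 + R_A) / 2.

Degree is the unweighted edge count of a node, normalized by n - 1;
betweenness is the exact (Brandes) sum over unordered node pairs of the
fraction of shortest paths through the node, normalized by (n-1)(n-2)/2.
Normalization uses n = all nodes of the window network, isolates included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import networkx as nx
import pandas as pd

from .build import NetworkSeries, WindowNetwork, africa_subgraph
from .errors import UndefinedMetricError

#: Node predicate selecting African institutions.
def is_african_node(node, data) -> bool:
    return bool(data.get("is_african"))


NodePredicate = Callable[[object, dict], bool]


# ---------------------------------------------------------------- connectivity

def largest_component(net: WindowNetwork) -> frozenset:
    """Node set of the largest connected component.

    Ties on size are broken deterministically in favour of the
    lexicographically smallest sorted member list.
    """
    comps = list(nx.connected_components(net.graph))
    if not comps:
        return frozenset()
    return frozenset(min(comps, key=lambda c: (-len(c), sorted(c))))


def pct_group_in_lcc(net: WindowNetwork, group: NodePredicate) -> float:
    """Percentage of group members (isolates included) inside the LCC."""
    members = [n for n, d in net.graph.nodes(data=True) if group(n, d)]
    if not members:
        raise UndefinedMetricError("group is empty in this network")
    lcc = largest_component(net)
    return 100.0 * sum(1 for n in members if n in lcc) / len(members)


def avg_path_length(
    net: WindowNetwork, pair_group: Optional[NodePredicate] = None
) -> float:
    """Mean shortest-path length over unordered pairs of group members in the LCC.

    ``pair_group=None`` averages over all LCC node pairs.
    """
    lcc = largest_component(net)
    sub = net.graph.subgraph(lcc)
    if pair_group is None:
        members = sorted(lcc)
    else:
        members = sorted(n for n in lcc if pair_group(n, net.graph.nodes[n]))
    if len(members) < 2:
        raise UndefinedMetricError("fewer than 2 group members in the LCC")
    member_set = set(members)
    total, npairs = 0, 0
    for i, src in enumerate(members):
        dist = nx.single_source_shortest_path_length(sub, src)
        for tgt in members[i + 1 :]:
            total += dist[tgt]
            npairs += 1
    assert npairs == len(member_set) * (len(member_set) - 1) // 2
    return total / npairs


@dataclass
class ConnectivityReport:
    window: str
    variant: str  # "whole-network" | "africa-only"
    n_nodes: int
    n_african: int
    lcc_size: int
    pct_african_in_lcc: float | None
    avg_path_length_african_pairs: float | None


def connectivity_report(net: WindowNetwork, variant: str = "whole-network") -> ConnectivityReport:
    """LCC share of African institutions and their average path length."""
    target = net if variant == "whole-network" else africa_subgraph(net)
    n_african = sum(1 for _, d in target.graph.nodes(data=True) if d.get("is_african"))
    try:
        pct = pct_group_in_lcc(target, is_african_node)
    except UndefinedMetricError:
        pct = None
    try:
        apl = avg_path_length(target, is_african_node)
    except UndefinedMetricError:
        apl = None
    return ConnectivityReport(
        window=net.label,
        variant=variant,
        n_nodes=target.number_of_nodes(),
        n_african=n_african,
        lcc_size=len(largest_component(target)),
        pct_african_in_lcc=pct,
        avg_path_length_african_pairs=apl,
    )


# ---------------------------------------------------------------- mixing

@dataclass
class MixingSummary:
    """Tie counts over the Africa / non-Africa partition and derived indices."""

    window: str
    i_a: int  # Africa-Africa ties
    e_a: int  # Africa-nonAfrica ties
    i_n: int  # nonAfrica-nonAfrica ties
    e_i_index: float | None
    regionalization: float | None
    internal_proportion: float | None


def e_i_index(external: int, internal: int) -> float:
    if external + internal == 0:
        raise UndefinedMetricError("no ties: E-I index undefined")
    return (external - internal) / (external + internal)


def regionalization_index(i_a: int, e_a: int) -> float:
    if 2 * i_a + e_a == 0:
        raise UndefinedMetricError("no African ties: regionalization undefined")
    return (2 * i_a - e_a) / (2 * i_a + e_a)


def internal_tie_proportion(r: float) -> float:
    """Average within-region tie proportion implied by a regionalization index."""
    return (1.0 + r) / 2.0


def mixing_summary(net: WindowNetwork) -> MixingSummary:
    """Classify every unique tie into I_A / E_A / I_N and derive the indices.

    Windows with a zero denominator yield ``None`` for the affected index
    (propagated to reports as missing), never a silent 0.
    """
    i_a = e_a = i_n = 0
    nodes = net.graph.nodes
    for u, v in net.graph.edges():
        du, dv = nodes[u], nodes[v]
        if "is_african" not in du or "is_african" not in dv:
            missing = u if "is_african" not in du else v
            raise UndefinedMetricError(f"node {missing!r} lacks a region flag")
        a, b = bool(du["is_african"]), bool(dv["is_african"])
        if a and b:
            i_a += 1
        elif a or b:
            e_a += 1
        else:
            i_n += 1
    try:
        ei = e_i_index(external=e_a, internal=i_a + i_n)
    except UndefinedMetricError:
        ei = None
    try:
        r = regionalization_index(i_a, e_a)
        prop = internal_tie_proportion(r)
    except UndefinedMetricError:
        r = prop = None
    return MixingSummary(
        window=net.label,
        i_a=i_a,
        e_a=e_a,
        i_n=i_n,
        e_i_index=ei,
        regionalization=r,
        internal_proportion=prop,
    )


# ---------------------------------------------------------------- centrality

def degree_centrality(net: WindowNetwork) -> dict:
    """Unweighted degree for every node."""
    return dict(net.graph.degree())


def normalized_degree(net: WindowNetwork) -> dict:
    """Degree divided by n - 1, n = all nodes in the window (isolates too)."""
    n = net.number_of_nodes()
    if n < 2:
        raise UndefinedMetricError("degree normalization undefined for n < 2")
    return {v: d / (n - 1) for v, d in net.graph.degree()}


def betweenness_centrality(net: WindowNetwork) -> dict:
    """Exact betweenness: sum over unordered pairs s != t != v of
    sigma_st(v) / sigma_st, pairs in other components contributing 0."""
    return nx.betweenness_centrality(net.graph, normalized=False)


def normalized_betweenness(net: WindowNetwork) -> dict:
    """Betweenness divided by (n-1)(n-2)/2, the maximum for a node in a
    network with the same number of nodes."""
    n = net.number_of_nodes()
    if n < 3:
        raise UndefinedMetricError("betweenness normalization undefined for n < 3")
    denom = (n - 1) * (n - 2) / 2.0
    return {v: b / denom for v, b in betweenness_centrality(net).items()}


def _competition_ranks(scores: dict) -> dict:
    """Competition ranking ('1,2,2,4'), 1 = highest score; deterministic."""
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    ranks, prev_score, prev_rank = {}, None, 0
    for i, (node, score) in enumerate(ordered, start=1):
        rank = prev_rank if score == prev_score else i
        ranks[node] = rank
        prev_score, prev_rank = score, rank
    return ranks


def centrality_table(net: WindowNetwork, group: NodePredicate = is_african_node) -> pd.DataFrame:
    """Per-institution centrality table for one window.

    Raw and normalized degree and betweenness for every node, plus
    within-group competition ranks (columns ``africa_rank_*``; NaN outside
    the group).
    """
    deg = degree_centrality(net)
    btw = betweenness_centrality(net)
    n = net.number_of_nodes()
    deg_norm = {v: (d / (n - 1) if n >= 2 else math.nan) for v, d in deg.items()}
    bdenom = (n - 1) * (n - 2) / 2.0 if n >= 3 else math.nan
    btw_norm = {v: b / bdenom for v, b in btw.items()}
    members = {v for v, d in net.graph.nodes(data=True) if group(v, d)}
    rank_deg = _competition_ranks({v: deg[v] for v in members})
    rank_btw = _competition_ranks({v: btw[v] for v in members})
    rows = [
        {
            "window": net.label,
            "institution": v,
            "name": net.graph.nodes[v].get("name", v),
            "is_african": bool(net.graph.nodes[v].get("is_african")),
            "degree": deg[v],
            "betweenness": btw[v],
            "degree_norm": deg_norm[v],
            "betweenness_norm": btw_norm[v],
            "africa_rank_degree": rank_deg.get(v, math.nan),
            "africa_rank_betweenness": rank_btw.get(v, math.nan),
        }
        for v in sorted(net.graph.nodes)
    ]
    return pd.DataFrame(rows)


def rank_and_select_central(
    series: NetworkSeries,
    group: NodePredicate = is_african_node,
    top_k: int = 3,
) -> tuple[set, pd.DataFrame]:
    """Identify the central group institutions across a network series.

    The central set contains every group institution that reaches a
    within-group competition rank <= ``top_k`` in either degree or
    betweenness in any window. The returned table holds one row per
    (window, institution) restricted to the central set, shaped like a
    rank-evolution table.
    """
    if not any(
        group(v, d) for net in series for v, d in net.graph.nodes(data=True)
    ):
        raise UndefinedMetricError("group is empty in every window")
    tables = [centrality_table(net, group) for net in series]
    full = pd.concat(tables, ignore_index=True)
    hit = (full["africa_rank_degree"] <= top_k) | (
        full["africa_rank_betweenness"] <= top_k
    )
    central = set(full.loc[hit, "institution"])
    table = full[full["institution"].isin(central)].reset_index(drop=True)
    return central, table


# ---------------------------------------------------------------- series reports

def mixing_series(series: NetworkSeries) -> pd.DataFrame:
    return pd.DataFrame([vars(mixing_summary(net)) for net in series])


def connectivity_series(series: NetworkSeries) -> pd.DataFrame:
    rows = []
    for net in series:
        rows.append(vars(connectivity_report(net, "whole-network")))
        rows.append(vars(connectivity_report(net, "africa-only")))
    return pd.DataFrame(rows)
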