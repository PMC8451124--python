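"""Local network neighbourhoods (ego networks) of central institutions.

The local neighbourhood of an institution is the set of its collaborators
together with the ties among those collaborators. The ego itself is
excluded when computing the component structure of the neighbourhood —
otherwise every neighbour would be connected through the ego and isolated
collaborators or small satellite components could never be seen.

Composition percentages (share of African neighbours, share of
nonacademic neighbours, i.e., sector other than university) are always
taken over the full, unfiltered collaborator set, while the neighbourhood
subgraph may be restricted to one region (e.g., African collaborators
only) for structural inspection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import networkx as nx
import pandas as pd

from .build import NetworkSeries, WindowNetwork
from .errors import CoauthnetError
from .metrics import NodePredicate


@dataclass
class EgoProfile:
    ego: str
    window: str
    neighbors: tuple  # after any region filter, sorted
    alter_edges: tuple  # ties among (filtered) neighbors, canonical order
    component_sizes: tuple  # ego-removed neighbourhood components, descending
    pct_african: float | None  # over ALL neighbors, unfiltered
    pct_nonacademic: float | None  # sector != university, over ALL neighbors


def ego_profile(
    net: WindowNetwork,
    ego: str,
    region_filter: Optional[NodePredicate] = None,
) -> EgoProfile:
    """Profile one institution's local neighbourhood in one window.

    ``region_filter`` restricts the structural part (neighbour set, ties
    among neighbours, component sizes); the composition percentages are
    computed over all collaborators regardless of the filter. An ego with
    no collaborators yields an empty profile, not an error.
    """
    g = net.graph
    if ego not in g:
        raise CoauthnetError(f"ego {ego!r} not present in window {net.label}")
    all_neighbors = sorted(g.neighbors(ego))
    if region_filter is None:
        kept = all_neighbors
    else:
        kept = [n for n in all_neighbors if region_filter(n, g.nodes[n])]
    sub: nx.Graph = g.subgraph(kept)  # ego excluded by construction
    comp_sizes = tuple(
        sorted((len(c) for c in nx.connected_components(sub)), reverse=True)
    )
    if all_neighbors:
        pct_african = 100.0 * sum(
            1 for n in all_neighbors if g.nodes[n].get("is_african")
        ) / len(all_neighbors)
        pct_nonacademic = 100.0 * sum(
            1 for n in all_neighbors if g.nodes[n].get("sector") != "university"
        ) / len(all_neighbors)
    else:
        pct_african = pct_nonacademic = None
    return EgoProfile(
        ego=ego,
        window=net.label,
        neighbors=tuple(kept),
        alter_edges=tuple(sorted(tuple(sorted(e)) for e in sub.edges())),
        component_sizes=comp_sizes,
        pct_african=pct_african,
        pct_nonacademic=pct_nonacademic,
    )


def ego_composition_series(
    series: NetworkSeries,
    egos,
    region_filter: Optional[NodePredicate] = None,
) -> pd.DataFrame:
    """One row per (ego, window) the ego appears in.

    Columns mirror a composition-over-time table: neighbour counts,
    component sizes of the (optionally region-filtered) neighbourhood, and
    the African / nonacademic shares of the full collaborator set.
    """
    rows = []
    for net in series:
        for ego in sorted(egos):
            if ego not in net.graph:
                continue
            p = ego_profile(net, ego, region_filter)
            rows.append(
                {
                    "window": p.window,
                    "ego": p.ego,
                    "n_neighbors": len(p.neighbors),
                    "n_alter_edges": len(p.alter_edges),
                    "component_sizes": ",".join(map(str, p.component_sizes)),
                    "pct_african": p.pct_african,
                    "pct_nonacademic": p.pct_nonacademic,
                }
            )
    return pd.DataFrame(rows)
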