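"""Shared fixtures and graph-building helpers."""

from __future__ import annotations

import networkx as nx
import pytest

from coauthnet.build import WindowNetwork
from coauthnet.records import AffiliationMention, Corpus, PublicationRecord
from coauthnet.resolve import Institution


def make_network(
    edges,
    nodes=None,
    african=(),
    sectors=None,
    window=(2008, 2009),
) -> WindowNetwork:
    """Build a WindowNetwork from an edge list plus attribute sets."""
    g = nx.Graph()
    african = set(african)
    sectors = sectors or {}
    for n in nodes or []:
        g.add_node(n)
    for u, v in edges:
        g.add_edge(u, v, weight=1)
    for n in g.nodes:
        g.nodes[n]["is_african"] = n in african
        g.nodes[n]["sector"] = sectors.get(n, "university")
        g.nodes[n]["country"] = "ZA" if n in african else "GB"
        g.nodes[n]["name"] = str(n)
    return WindowNetwork(window=window, graph=g)


def make_corpus(papers, regions, sectors=None) -> tuple[Corpus, dict]:
    """Corpus + registry from [(pub_id, year, [inst_id, ...]), ...].

    ``regions`` maps institution id -> True (African) / False; mentions are
    emitted pre-resolved (canonical_id and parsed_country populated).
    """
    sectors = sectors or {}
    corpus = Corpus()
    years: dict[str, set] = {}
    for pub_id, year, insts in papers:
        mentions = [
            AffiliationMention(
                raw_text=f"{i}, Town, {'South Africa' if regions[i] else 'United Kingdom'}",
                parsed_country="ZA" if regions[i] else "GB",
                raw_institution=i,
                canonical_id=i,
            )
            for i in insts
        ]
        corpus.records[pub_id] = PublicationRecord(
            pub_id=pub_id,
            title=pub_id,
            year=year,
            author_count=len(insts),
            mentions=mentions,
        )
        for i in insts:
            years.setdefault(i, set()).add(year)
    registry = {
        i: Institution(
            canonical_id=i,
            canonical_name=i,
            country="ZA" if regions[i] else "GB",
            is_african=regions[i],
            sector=sectors.get(i, "university"),
            first_pub_year=min(ys),
            active_years=ys,
        )
        for i, ys in years.items()
    }
    return corpus, registry


@pytest.fixture
def three_paper_corpus():
    """The worked micro-example: three papers, three multi-year institutions."""
    return make_corpus(
        [
            ("P1", 2008, ["A", "B"]),
            ("P2", 2009, ["B", "C"]),
            ("P3", 2011, ["A", "C"]),
        ],
        regions={"A": True, "B": True, "C": False},
    )


@pytest.fixture(scope="session")
def small_synth():
    """A scaled-down generated corpus shared across tests (read-only)."""
    from coauthnet.synth import SynthConfig, generate_corpus

    config = SynthConfig(
        seed=20240915,
        first_year=2008,
        last_year=2013,
        african_start=20,
        african_end=80,
        nonafrican_start=25,
        nonafrican_end=160,
        papers_start=30,
        papers_end=150,
        name_noise_rate=0.0,
    )
    corpus, truth = generate_corpus(config)
    return config, corpus, truth
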