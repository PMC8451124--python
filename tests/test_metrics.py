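"""Connectivity, mixing indices and centrality against independent oracles."""

import itertools
import random

import networkx as nx
import pytest

from coauthnet.build import NetworkSeries
from coauthnet.errors import UndefinedMetricError
from coauthnet.metrics import (
    avg_path_length,
    betweenness_centrality,
    centrality_table,
    degree_centrality,
    e_i_index,
    internal_tie_proportion,
    is_african_node,
    largest_component,
    mixing_summary,
    normalized_betweenness,
    normalized_degree,
    pct_group_in_lcc,
    rank_and_select_central,
    regionalization_index,
)

from conftest import make_network


# ---------------------------------------------------------- oracles

def bfs_components(g: nx.Graph):
    """Flood-fill components, independent of the library implementation."""
    seen, comps = set(), []
    for start in g.nodes:
        if start in seen:
            continue
        comp, frontier = {start}, [start]
        while frontier:
            nxt = []
            for u in frontier:
                for v in g.adj[u]:
                    if v not in comp:
                        comp.add(v)
                        nxt.append(v)
            frontier = nxt
        seen |= comp
        comps.append(comp)
    return comps


def bfs_distances(g: nx.Graph, src):
    dist, frontier, d = {src: 0}, [src], 0
    while frontier:
        d += 1
        nxt = []
        for u in frontier:
            for v in g.adj[u]:
                if v not in dist:
                    dist[v] = d
                    nxt.append(v)
        frontier = nxt
    return dist


def brute_betweenness(g: nx.Graph):
    """Exhaustive shortest-path enumeration (small graphs only): for every
    unordered pair, enumerate all simple paths, keep the shortest ones, and
    credit interior nodes with their fraction."""
    btw = {v: 0.0 for v in g.nodes}
    nodes = sorted(g.nodes)
    for s, t in itertools.combinations(nodes, 2):
        paths = list(nx.all_simple_paths(g, s, t))
        if not paths:
            continue
        dmin = min(len(p) for p in paths)
        shortest = [p for p in paths if len(p) == dmin]
        for p in shortest:
            for v in p[1:-1]:
                btw[v] += 1.0 / len(shortest)
    return btw


# ---------------------------------------------------------- LCC

class TestLargestComponent:
    def test_tie_broken_to_lexicographically_smallest(self):
        net = make_network([("A", "B"), ("B", "C"), ("A", "C"),
                            ("D", "E"), ("E", "F"), ("D", "F")])
        assert largest_component(net) == {"A", "B", "C"}

    def test_connected_graph_returns_all(self):
        net = make_network([("A", "B"), ("B", "C")])
        assert largest_component(net) == {"A", "B", "C"}

    def test_matches_bfs_oracle_on_random_graph(self):
        g = nx.gnp_random_graph(300, 0.004, seed=11)
        net = make_network(list(g.edges), nodes=list(g.nodes))
        expected = max(bfs_components(net.graph), key=len)
        got = largest_component(net)
        assert len(got) == len(expected) and got == expected


class TestPctGroupInLcc:
    def test_all_in_one_component(self):
        net = make_network([("A", "B")], african={"A", "B"})
        assert pct_group_in_lcc(net, is_african_node) == 100.0

    def test_two_equal_cliques_split(self):
        net = make_network(
            [("A", "B"), ("C", "D")], african={"A", "B", "C", "D"}
        )
        assert pct_group_in_lcc(net, is_african_node) == 50.0

    def test_isolates_count_in_denominator(self):
        net = make_network([("A", "B")], nodes=["I"], african={"A", "B", "I"})
        assert pct_group_in_lcc(net, is_african_node) == pytest.approx(200 / 3)

    def test_empty_group_signalled(self):
        net = make_network([("A", "B")])
        with pytest.raises(UndefinedMetricError):
            pct_group_in_lcc(net, is_african_node)


class TestAvgPathLength:
    def test_path_graph_hand_value(self):
        net = make_network([("u", "v"), ("v", "w")], african={"u", "v", "w"})
        assert avg_path_length(net, is_african_node) == pytest.approx(4 / 3)

    def test_complete_graph_is_one(self):
        net = make_network(
            list(itertools.combinations("abcde", 2)), african=set("abcde")
        )
        assert avg_path_length(net, is_african_node) == 1.0

    def test_matches_all_pairs_bfs_oracle(self):
        g = nx.connected_watts_strogatz_graph(150, 4, 0.2, seed=3)
        afr = {n for n in g.nodes if n % 3 == 0}
        net = make_network(list(g.edges), african=afr)
        total = npairs = 0
        members = sorted(afr)
        for i, s in enumerate(members):
            dist = bfs_distances(net.graph, s)
            for t in members[i + 1 :]:
                total += dist[t]
                npairs += 1
        assert avg_path_length(net, is_african_node) == pytest.approx(
            total / npairs, abs=1e-12
        )

    def test_single_member_signalled(self):
        net = make_network([("A", "B")], african={"A"})
        with pytest.raises(UndefinedMetricError):
            avg_path_length(net, is_african_node)


# ---------------------------------------------------------- mixing

class TestMixing:
    def test_balanced_square(self):
        net = make_network(
            [("a1", "a2"), ("a1", "b1"), ("a2", "b2"), ("b1", "b2")],
            african={"a1", "a2"},
        )
        m = mixing_summary(net)
        assert (m.i_a, m.e_a, m.i_n) == (1, 2, 1)
        assert m.e_i_index == 0.0
        assert m.regionalization == 0.0
        assert m.internal_proportion == 0.5

    def test_all_internal_boundary(self):
        net = make_network([("a1", "a2"), ("a2", "a3")], african={"a1", "a2", "a3"})
        m = mixing_summary(net)
        assert m.regionalization == 1.0 and m.e_i_index == -1.0

    def test_printed_transform_pairs(self):
        assert round(internal_tie_proportion(-0.46), 2) == 0.27
        # the 2018-2019 value prints as 0.42 at two decimals (half-up)
        assert internal_tie_proportion(-0.17) == pytest.approx(0.415)

    def test_no_ties_yields_missing_not_zero(self):
        net = make_network([], nodes=["a", "b"], african={"a"})
        m = mixing_summary(net)
        assert m.e_i_index is None and m.regionalization is None

    def test_missing_region_flag_named(self):
        net = make_network([("a", "b")])
        del net.graph.nodes["b"]["is_african"]
        with pytest.raises(UndefinedMetricError, match="b"):
            mixing_summary(net)

    def test_index_invariants_on_random_counts(self):
        rng = random.Random(7)
        for _ in range(200):
            i_a, e_a = rng.randint(0, 50), rng.randint(0, 50)
            if 2 * i_a + e_a == 0:
                continue
            r = regionalization_index(i_a, e_a)
            assert -1.0 <= r <= 1.0
            assert r == pytest.approx(1 - 2 * e_a / (2 * i_a + e_a))
            # transform round-trips exactly
            assert 2 * internal_tie_proportion(r) - 1 == pytest.approx(r)

    def test_regionalization_monotone_in_internal_ties(self):
        rng = random.Random(13)
        for _ in range(100):
            i_a, e_a = rng.randint(0, 20), rng.randint(1, 20)
            assert regionalization_index(i_a + 1, e_a) > regionalization_index(i_a, e_a)

    def test_invariant_to_relabeling_and_duplicate_publications(self):
        edges = [("x", "y"), ("y", "z"), ("x", "z"), ("z", "w")]
        net = make_network(edges, african={"x", "y"})
        m1 = mixing_summary(net)
        relabel = {"x": "n1", "y": "n2", "z": "n3", "w": "n4"}
        net2 = make_network(
            [(relabel[u], relabel[v]) for u, v in edges], african={"n1", "n2"}
        )
        m2 = mixing_summary(net2)
        assert (m1.i_a, m1.e_a, m1.i_n) == (m2.i_a, m2.e_a, m2.i_n)
        # duplicating a publication raises weights but adds no parallel edge
        net.graph["x"]["y"]["weight"] += 1
        m3 = mixing_summary(net)
        assert (m3.e_i_index, m3.regionalization) == (m1.e_i_index, m1.regionalization)

    def test_e_i_zero_denominator_signalled(self):
        with pytest.raises(UndefinedMetricError):
            e_i_index(0, 0)


# ---------------------------------------------------------- centrality

class TestDegree:
    def test_star_center_and_isolate(self):
        net = make_network(
            [("c", "l1"), ("c", "l2"), ("c", "l3")], nodes=["i"]
        )
        deg, nd = degree_centrality(net), normalized_degree(net)
        assert deg["c"] == 3 and nd["c"] == pytest.approx(3 / 4)
        assert deg["i"] == 0 and nd["i"] == 0.0

    def test_handshake_identity(self, small_synth):
        from coauthnet.build import build_series
        from coauthnet.resolve import resolve_corpus

        config, corpus, _ = small_synth
        registry, _ = resolve_corpus(corpus)
        net = build_series(corpus, registry, config.first_year, config.last_year)[-1]
        deg = degree_centrality(net)
        assert sum(deg.values()) == 2 * net.number_of_edges()

    def test_tiny_graph_normalization_signalled(self):
        net = make_network([], nodes=["a"])
        with pytest.raises(UndefinedMetricError):
            normalized_degree(net)


class TestBetweenness:
    def test_path_and_star_hand_values(self):
        path = make_network([("u", "v"), ("v", "w")])
        assert betweenness_centrality(path)["v"] == pytest.approx(1.0)
        star = make_network([("c", "a"), ("c", "b"), ("c", "d")])
        btw = betweenness_centrality(star)
        assert btw["c"] == pytest.approx(3.0)
        assert normalized_betweenness(star)["c"] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        rng = random.Random(5)
        for i in range(30):
            n = rng.randint(4, 9)
            g = nx.gnp_random_graph(n, 0.45, seed=100 + i)
            net = make_network(list(g.edges), nodes=list(g.nodes))
            expected = brute_betweenness(net.graph)
            got = betweenness_centrality(net)
            for v in g.nodes:
                assert got[v] == pytest.approx(expected[v], abs=1e-9)

    def test_cut_vertex_between_cliques_is_strict_maximum(self):
        left = list(itertools.combinations(["a", "b", "c"], 2))
        right = list(itertools.combinations(["x", "y", "z"], 2))
        bridge = [("c", "m"), ("m", "x")]
        net = make_network(left + right + bridge)
        btw = betweenness_centrality(net)
        assert btw["m"] > max(v for k, v in btw.items() if k != "m")

    def test_disconnected_pairs_contribute_zero(self):
        net = make_network([("a", "b"), ("b", "c"), ("x", "y")])
        assert betweenness_centrality(net)["b"] == pytest.approx(1.0)

    def test_small_graph_normalization_signalled(self):
        net = make_network([("a", "b")])
        with pytest.raises(UndefinedMetricError):
            normalized_betweenness(net)


class TestRanking:
    def _series(self):
        # window 1: H1 dominates degree; window 2: H2 takes over
        w1 = make_network(
            [("H1", x) for x in ("a", "b", "c", "n1")]
            + [("H2", "a"), ("H3", "a"), ("H3", "b"), ("K", "a")],
            african={"H1", "H2", "H3", "K", "a", "b", "c"},
            window=(2008, 2009),
        )
        w2 = make_network(
            [("H2", x) for x in ("a", "b", "c", "d", "n1")]
            + [("H1", "a"), ("H3", "a"), ("H3", "b"), ("H3", "c"), ("K", "a")],
            african={"H1", "H2", "H3", "K", "a", "b", "c", "d"},
            window=(2009, 2010),
        )
        return NetworkSeries(windows=[w1, w2])

    def test_competition_ranking_shares_minimum_rank(self):
        net = make_network(
            [("A", "B"), ("A", "C"), ("B", "C"), ("D", "A")],
            african={"A", "B", "C", "D"},
        )
        table = centrality_table(net).set_index("institution")
        # degrees: A=3, B=2, C=2, D=1 -> ranks 1, 2, 2, 4
        assert list(table["africa_rank_degree"].loc[["A", "B", "C", "D"]]) == [1, 2, 2, 4]

    def test_top_k_membership_rule(self):
        central, table = rank_and_select_central(self._series(), top_k=3)
        assert {"H1", "H2", "H3"} <= central
        # K never reaches rank <= 3 on either measure in either window
        assert "K" not in central
        assert set(table["institution"]) == central

    def test_always_first_in_degree_is_central(self):
        central, _ = rank_and_select_central(self._series(), top_k=1)
        assert "H1" in central and "H2" in central

    def test_normalization_uses_window_node_count(self):
        net = make_network([("c", "a"), ("c", "b")], nodes=["iso"], african={"c"})
        table = centrality_table(net).set_index("institution")
        assert table.loc["c", "degree_norm"] == pytest.approx(2 / 3)  # n=4 with isolate
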