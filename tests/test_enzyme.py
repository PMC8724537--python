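"""EC extraction, pathway-derived enzyme graph, topology, hubs, communities."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from growthnet import (
    build_network,
    detect_communities,
    detect_hubs,
    extract_ec,
    simulate_pathway_db,
    topology,
)
from growthnet.enzyme import EnzymeNetwork, TopologyReport


def _annot(ec_lists):
    return pd.DataFrame(
        {
            "chrom": "chrom01",
            "start": np.arange(1, len(ec_lists) + 1) * 1000,
            "end": np.arange(1, len(ec_lists) + 1) * 1000 + 500,
            "strand": "+",
            "product": "p",
            "GO": "",
            "EC": ec_lists,
        },
        index=pd.Index([f"g{i}" for i in range(len(ec_lists))], name="gene_id"),
    )


def _net_from_graph(g: nx.Graph) -> EnzymeNetwork:
    dg = nx.DiGraph()
    dg.add_nodes_from(g.nodes)
    dg.add_edges_from(g.edges)
    sg = nx.Graph(g)
    return EnzymeNetwork(digraph=dg, graph=sg, query_ecs=set(), pathways={})


class TestExtractEc:
    def test_nineteen_distinct_ecs_from_nineteen_genes(self):
        ecs = [f"2.7.1.{i}" for i in range(1, 20)]
        prov, partial = extract_ec(_annot(ecs))
        assert len(prov) == 19
        assert partial == set()

    def test_duplicate_ec_merges_provenance(self):
        prov, _ = extract_ec(_annot(["1.1.1.1", "1.1.1.1"]))
        assert prov["1.1.1.1"] == {"g0", "g1"}

    def test_partial_ec_kept_but_flagged(self):
        prov, partial = extract_ec(_annot(["4.2.3.-"]))
        assert "4.2.3.-" in prov
        assert partial == {"4.2.3.-"}

    def test_malformed_ec_rejected_with_warning(self):
        with pytest.warns(UserWarning, match="2.7.x"):
            prov, _ = extract_ec(_annot(["2.7.x"]))
        assert prov == {}

    def test_genes_without_ec_skipped(self):
        prov, _ = extract_ec(_annot(["", "3.5.1.116"]))
        assert list(prov) == ["3.5.1.116"]


class TestBuildNetwork:
    def _db(self, rows):
        return pd.DataFrame(
            rows, columns=["pathway_id", "reaction_id", "ec", "substrates", "products"]
        )

    def test_shared_noncurrency_compound_creates_directed_edge(self):
        db = self._db(
            [
                ["p1", "r1", "1.1.1.1", "C1", "C2"],
                ["p1", "r2", "2.2.2.2", "C2", "C3"],
            ]
        )
        net = build_network({"1.1.1.1"}, db)
        assert list(net.digraph.edges) == [("1.1.1.1", "2.2.2.2")]

    def test_currency_compound_never_creates_edge(self):
        db = self._db(
            [
                ["p1", "r1", "1.1.1.1", "C1", "ATP"],
                ["p1", "r2", "2.2.2.2", "ATP", "C3"],
            ]
        )
        net = build_network({"1.1.1.1"}, db)
        assert net.digraph.number_of_edges() == 0

    def test_all_pathway_members_become_nodes(self):
        db = self._db(
            [
                ["p1", "r1", "1.1.1.1", "C1", "C2"],
                ["p1", "r2", "2.2.2.2", "C2", "C3"],
                ["p1", "r3", "3.3.3.3", "C9", "C8"],  # disconnected member
                ["p2", "r4", "4.4.4.4", "C5", "C6"],  # pathway without queries
            ]
        )
        net = build_network({"1.1.1.1"}, db)
        assert set(net.digraph.nodes) == {"1.1.1.1", "2.2.2.2", "3.3.3.3"}

    def test_toy_db_counts_match_hand_enumeration(self):
        db = self._db(
            [
                ["p1", "r1", "1.1.1.1", "C1", "C2"],
                ["p1", "r1b", "1.1.1.1", "C1", "C2"],
                ["p1", "r2", "2.2.2.2", "C2", "C3"],
                ["p1", "r3", "3.3.3.3", "C3;C2", "C4"],
                ["p2", "r4", "1.1.1.1", "C7", "C8"],
                ["p2", "r5", "5.5.5.5", "C8", "C9"],
            ]
        )
        net = build_network({"2.2.2.2"}, db)
        # pathways p1 and p2 both contain queries? only p1 has 2.2.2.2
        assert set(net.digraph.nodes) == {"1.1.1.1", "2.2.2.2", "3.3.3.3"}
        assert set(net.digraph.edges) == {
            ("1.1.1.1", "2.2.2.2"),
            ("1.1.1.1", "3.3.3.3"),
            ("2.2.2.2", "3.3.3.3"),
        }

    def test_reversible_doubles_edges(self):
        db = self._db(
            [
                ["p1", "r1", "1.1.1.1", "C1", "C2"],
                ["p1", "r2", "2.2.2.2", "C2", "C3"],
            ]
        )
        net = build_network({"1.1.1.1"}, db, reversible=True)
        assert set(net.digraph.edges) == {
            ("1.1.1.1", "2.2.2.2"),
            ("2.2.2.2", "1.1.1.1"),
        }

    def test_no_matching_pathway_warns_empty(self):
        db = self._db([["p1", "r1", "1.1.1.1", "C1", "C2"]])
        with pytest.warns(UserWarning, match="no pathway"):
            net = build_network({"9.9.9.9"}, db)
        assert len(net.digraph) == 0


def _bfs_oracle(g: nx.Graph):
    """Exhaustive shortest-path enumeration: betweenness (normalised), stress
    (exact integers) and eccentricity, independent of the implementation."""
    nodes = list(g.nodes)
    n = len(nodes)
    paths = {}
    for s in nodes:
        for t in nodes:
            if s != t and nx.has_path(g, s, t):
                paths[(s, t)] = list(nx.all_shortest_paths(g, s, t))
    betw = {v: 0.0 for v in nodes}
    stress = {v: 0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            if (s, t) not in paths:
                continue
            ps = paths[(s, t)]
            for v in nodes:
                if v in (s, t):
                    continue
                cnt = sum(1 for p in ps if v in p)
                stress[v] += cnt
                betw[v] += cnt / len(ps)
    norm = (n - 1) * (n - 2) / 2.0
    if norm > 0:
        betw = {v: b / norm for v, b in betw.items()}
    ecc = {}
    for v in nodes:
        comp_dists = [
            len(p[0]) - 1 for (s, t), p in paths.items() if s == v
        ]
        ecc[v] = max(comp_dists) if comp_dists else 0
    return betw, stress, ecc


class TestTopology:
    def test_path_graph_center(self):
        g = nx.path_graph(["A", "B", "C"])
        rep = topology(_net_from_graph(g))
        row = rep.table.loc["B"]
        assert row["betweenness"] == pytest.approx(1.0)
        assert row["stress"] == 1
        assert row["eccentricity"] == 1
        assert rep.diameter == 2

    def test_four_cycle_symmetry(self):
        g = nx.cycle_graph(4)
        rep = topology(_net_from_graph(g))
        assert rep.table["betweenness"].nunique() == 1
        assert (rep.table["neighborhood_connectivity"] == 2.0).all()
        assert (rep.table["degree"] == 2).all()

    def test_random_12_node_graph_matches_oracle(self):
        rng = np.random.default_rng(3)
        g = nx.gnp_random_graph(12, 0.3, seed=7)
        rep = topology(_net_from_graph(g))
        betw, stress, ecc = _bfs_oracle(g)
        for v in g.nodes:
            assert rep.table.loc[v, "stress"] == stress[v]
            assert rep.table.loc[v, "betweenness"] == pytest.approx(betw[v], abs=1e-12)
            assert rep.table.loc[v, "eccentricity"] == ecc[v]

    def test_mean_neighbors_equals_2e_over_n(self):
        g = nx.gnp_random_graph(15, 0.25, seed=5)
        rep = topology(_net_from_graph(g))
        assert rep.mean_neighbors == pytest.approx(
            2 * g.number_of_edges() / g.number_of_nodes()
        )

    def test_disconnected_components_measured_within_component(self):
        g = nx.Graph([("A", "B"), ("C", "D"), ("D", "E")])
        rep = topology(_net_from_graph(g))
        assert rep.table.loc["A", "eccentricity"] == 1
        assert rep.table.loc["C", "eccentricity"] == 2
        assert rep.diameter == 2  # largest component C-D-E


class TestDetectHubs:
    def _report(self, degrees):
        tab = pd.DataFrame(
            {"degree": degrees}, index=[f"e{i}" for i in range(len(degrees))]
        )
        return TopologyReport(
            table=tab, n_nodes=len(degrees), n_edges=0, mean_neighbors=0.0,
            mean_degree_directed=0.0, diameter=0,
        )

    def test_single_outlier_detected(self):
        assert detect_hubs(self._report([1, 1, 1, 1, 20])) == ["e4"]

    def test_uniform_degrees_give_no_hubs(self):
        assert detect_hubs(self._report([3] * 8)) == []

    def test_power_law_tail_matches_direct_quartile_rule(self):
        rng = np.random.default_rng(9)
        deg = np.concatenate(
            [rng.integers(1, 6, 50), rng.integers(30, 60, 3)]
        ).astype(float)
        hubs = detect_hubs(self._report(deg))
        q1, q3 = np.percentile(deg, [25, 75])
        expected = sorted(
            f"e{i}" for i in range(len(deg)) if deg[i] > q3 + 1.5 * (q3 - q1)
        )
        assert hubs == expected

    def test_hub_rule_is_scale_invariant(self):
        rng = np.random.default_rng(10)
        deg = rng.integers(1, 30, 40).astype(float)
        assert detect_hubs(self._report(deg)) == detect_hubs(self._report(deg * 7.0))

    def test_tiny_network_rejected(self):
        with pytest.raises(ValueError):
            detect_hubs(self._report([1, 2, 3]))


class TestDetectCommunities:
    def test_two_cliques_joined_by_bridge(self):
        g1 = nx.complete_graph(range(6))
        g2 = nx.complete_graph(range(6, 12))
        g = nx.union(g1, g2)
        g.add_edge(0, 6)
        ch = detect_communities(_net_from_graph(g), persistence_min=2, seed=0)
        communities = [frozenset(c) for c in ch.communities.values()]
        assert frozenset(range(6)) in communities
        assert frozenset(range(6, 12)) in communities

    def test_complete_graph_is_one_community_at_low_resolution(self):
        g = nx.complete_graph(8)
        ch = detect_communities(
            _net_from_graph(g), resolutions=np.array([0.1, 0.15, 0.2]),
            persistence_min=2, seed=0,
        )
        assert len(ch.communities) == 1
        assert set(next(iter(ch.communities.values()))) == set(range(8))

    def test_rerun_is_deterministic(self):
        g = nx.gnp_random_graph(30, 0.15, seed=11)
        net = _net_from_graph(g)
        a = detect_communities(net, seed=4)
        b = detect_communities(net, seed=4)
        assert {k: v for k, v in a.communities.items()} == dict(b.communities)
        assert a.persistence == b.persistence

    def test_minimum_community_size_enforced(self):
        g = nx.gnp_random_graph(25, 0.2, seed=12)
        ch = detect_communities(_net_from_graph(g), min_size=4, seed=1)
        for members in ch.communities.values():
            assert len(members) >= 4

    def test_edgeless_network_warns_empty(self):
        g = nx.empty_graph(5)
        with pytest.warns(UserWarning, match="edgeless"):
            ch = detect_communities(_net_from_graph(g))
        assert ch.communities == {}


class TestPipelineIntegration:
    def test_synthetic_pathways_build_connected_analysis(self):
        ecs = [f"2.7.1.{i}" for i in range(1, 20)]
        db = simulate_pathway_db(28, ecs, shared_compound_rate=0.6, seed=2)
        net = build_network(set(ecs[:5]), db)
        rep = topology(net)
        assert rep.n_nodes > 0
        largest = max(nx.connected_components(net.graph), key=len)
        assert rep.diameter == rep.table.loc[sorted(largest), "eccentricity"].max()
        if rep.n_edges > 0:
            ch = detect_communities(net, seed=3)
            assert all(len(m) >= 4 for m in ch.communities.values())
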