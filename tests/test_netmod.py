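"""Network construction, MCL clustering against a reference, hub extraction."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from convergene import netmod

from _oracles import reference_mcl


def edges_df(rows):
    return pd.DataFrame(rows, columns=["protein_a", "protein_b", "evidence_count"])


def two_clique_bridge():
    """Two 4-cliques joined by a single bridge edge (9 edges + bridge)."""
    g = nx.Graph()
    left = ["A1", "A2", "A3", "A4"]
    right = ["B1", "B2", "B3", "B4"]
    for grp in (left, right):
        for i, u in enumerate(grp):
            for v in grp[i + 1 :]:
                g.add_edge(u, v)
    g.add_edge("A1", "B1")
    return g, left, right


class TestBuildNetwork:
    def test_fallback_not_triggered_when_two_evidence_edge_exists(self):
        net = netmod.build_network(
            {"S"}, edges_df([("S", "X", 2), ("S", "Y", 1)])
        )
        assert set(map(frozenset, net.graph.edges)) == {frozenset({"S", "X"})}
        assert net.graph.edges["S", "X"]["provenance"] == "two_plus"

    def test_fallback_admits_single_validation_edges(self):
        net = netmod.build_network({"S"}, edges_df([("S", "Y", 1)]))
        assert set(map(frozenset, net.graph.edges)) == {frozenset({"S", "Y"})}
        assert net.graph.edges["S", "Y"]["provenance"] == "one_fallback"

    def test_self_loops_and_isolates_removed(self):
        net = netmod.build_network(
            {"S"}, edges_df([("S", "S", 5), ("S", "X", 3)])
        )
        assert sorted(net.graph.nodes) == ["S", "X"]

    def test_empty_seed_set_is_error(self):
        with pytest.raises(ValueError):
            netmod.build_network(set(), edges_df([("A", "B", 2)]))

    def test_matches_rule_by_rule_bruteforce(self):
        rng = np.random.default_rng(13)
        seeds = {f"S{i}" for i in range(10)}
        partners = [f"P{i}" for i in range(40)]
        rows = []
        for s in sorted(seeds):
            for p in rng.choice(partners, size=int(rng.integers(1, 6)), replace=False):
                rows.append((s, p, int(rng.integers(1, 4))))
        df = edges_df(rows)
        net = netmod.build_network(seeds, df)

        # independent rule-by-rule reconstruction
        pairs = {}
        for a, b, ev in rows:
            key = tuple(sorted((a, b)))
            pairs[key] = max(pairs.get(key, 0), ev)
        net_a = {k for k, ev in pairs.items() if ev >= 2}
        covered = {p for k in net_a for p in k if p in seeds}
        lonely = seeds - covered
        net_b = {
            k for k, ev in pairs.items()
            if k not in net_a and (k[0] in lonely or k[1] in lonely)
        }
        expected = net_a | net_b
        assert set(map(tuple, map(sorted, net.graph.edges))) == expected

    def test_invariant_to_edge_row_order(self):
        rows = [("S1", "P1", 2), ("S1", "P2", 1), ("S2", "P3", 1), ("S2", "P1", 3)]
        a = netmod.build_network({"S1", "S2"}, edges_df(rows))
        b = netmod.build_network({"S1", "S2"}, edges_df(rows[::-1]))
        pd.testing.assert_frame_equal(a.edge_frame(), b.edge_frame())


class TestAssignLayers:
    def test_multicompartment_resolved_by_priority(self):
        net = netmod.build_network({"S"}, edges_df([("S", "X", 2)]))
        netmod.assign_layers(net, {"S": ["nucleus", "plasma_membrane"]})
        assert net.graph.nodes["S"]["layer"] == "plasma_membrane"
        assert net.graph.nodes["X"]["layer"] == "unknown"

    def test_no_localization_means_all_unknown(self):
        net = netmod.build_network({"S"}, edges_df([("S", "X", 2)]))
        netmod.assign_layers(net, None)
        assert net.layer_counts() == {"unknown": 2}

    def test_per_layer_counts_match_planted_assignment(self):
        rng = np.random.default_rng(3)
        rows = [(f"S{i}", f"P{i}", 2) for i in range(20)]
        net = netmod.build_network({f"S{i}" for i in range(20)}, edges_df(rows))
        loc, expected = {}, {}
        for node in net.nodes:
            comp = netmod.DEFAULT_COMPARTMENT_PRIORITY[
                int(rng.integers(0, len(netmod.DEFAULT_COMPARTMENT_PRIORITY)))
            ]
            loc[node] = comp
            expected[comp] = expected.get(comp, 0) + 1
        netmod.assign_layers(net, loc)
        assert net.layer_counts() == dict(sorted(expected.items()))


def net_from_graph(g):
    return netmod.InteractionNetwork(graph=g)


class TestMCL:
    def test_two_clique_bridge_splits_at_bridge(self):
        g, left, right = two_clique_bridge()
        cs = netmod.mcl_cluster(net_from_graph(g), netmod.MCLParams(inflation=2.0))
        got = {frozenset(c) for c in cs.clusters}
        assert got == {frozenset(left), frozenset(right)}
        assert got == reference_mcl(g, 2.0)

    def test_single_node_is_singleton_cluster(self):
        g = nx.Graph()
        g.add_node("X")
        cs = netmod.mcl_cluster(net_from_graph(g))
        assert cs.clusters == [["X"]]

    @pytest.mark.parametrize("inflation", [1.5, 2.0, 4.0])
    def test_disjoint_cliques_stay_separate(self, inflation):
        g = nx.Graph()
        cliques = []
        for c in range(4):
            members = [f"C{c}N{i}" for i in range(4)]
            cliques.append(frozenset(members))
            for i, u in enumerate(members):
                for v in members[i + 1 :]:
                    g.add_edge(u, v)
        cs = netmod.mcl_cluster(net_from_graph(g), netmod.MCLParams(inflation=inflation))
        assert {frozenset(c) for c in cs.clusters} == set(cliques)

    def test_inflation_below_one_is_parameter_error(self):
        with pytest.raises(ValueError):
            netmod.MCLParams(inflation=1.0)

    def test_output_is_partition_of_nodes(self):
        g = nx.gnp_random_graph(40, 0.12, seed=2)
        g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
        g.remove_nodes_from(list(nx.isolates(g)))
        cs = netmod.mcl_cluster(net_from_graph(g))
        members = [n for c in cs.clusters for n in c]
        assert sorted(members) == sorted(g.nodes)  # disjoint cover

    def test_column_stochastic_after_each_inflation(self, monkeypatch):
        g, *_ = two_clique_bridge()
        recorded = []
        orig = netmod._column_normalize

        def spy(m):
            out = orig(m)
            recorded.append(out.sum(axis=0))
            return out

        monkeypatch.setattr(netmod, "_column_normalize", spy)
        netmod.mcl_cluster(net_from_graph(g))
        for colsums in recorded:
            assert np.allclose(colsums, 1.0, atol=1e-9)

    def test_inflation_sweep_never_decreases_cluster_count(self):
        g, *_ = two_clique_bridge()
        counts = [
            len(netmod.mcl_cluster(net_from_graph(g), netmod.MCLParams(inflation=i)))
            for i in (1.3, 2.0, 3.0, 5.0)
        ]
        assert counts == sorted(counts)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_reference_mcl_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 30))
        g = nx.gnp_random_graph(n, 0.2, seed=seed + 100)
        g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
        g.remove_nodes_from(list(nx.isolates(g)))
        if g.number_of_nodes() == 0:
            pytest.skip("degenerate draw")
        cs = netmod.mcl_cluster(net_from_graph(g), netmod.MCLParams(inflation=2.0))
        assert {frozenset(c) for c in cs.clusters} == reference_mcl(g, 2.0)


class TestFindHubs:
    def test_star_center_is_hub(self):
        g = nx.star_graph(5)
        g = nx.relabel_nodes(g, {0: "CENTER", **{i: f"LEAF{i}" for i in range(1, 6)}})
        net = net_from_graph(g)
        cs = netmod.ClusterSet(clusters=[sorted(g.nodes)], hubs={})
        assert netmod.find_hubs(cs, net) == {0: "CENTER"}

    def test_cycle_tie_breaks_lexicographically(self):
        g = nx.Graph([("B", "C"), ("C", "A"), ("A", "B")])
        cs = netmod.ClusterSet(clusters=[["A", "B", "C"]], hubs={})
        assert netmod.find_hubs(cs, net_from_graph(g)) == {0: "A"}

    def test_small_clusters_excluded_from_significant_report(self):
        cs = netmod.ClusterSet(
            clusters=[["A", "B", "C", "D", "E"], ["X", "Y"]], hubs={0: "A", 1: "X"}
        )
        assert cs.significant == [0]

    def test_hubs_match_bruteforce_degree_maxima(self):
        g = nx.gnp_random_graph(30, 0.2, seed=7)
        g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
        g.remove_nodes_from(list(nx.isolates(g)))
        net = net_from_graph(g)
        cs = netmod.mcl_cluster(net)
        for i, members in enumerate(cs.clusters):
            sub = g.subgraph(members)
            best = min(members,
                       key=lambda v: (-sub.degree(v), -g.degree(v), v))
            assert cs.hubs[i] == best
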