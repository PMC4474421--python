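"""Network construction, filtering, merging, clustering and path tracing."""

from __future__ import annotations

import numpy as np
import pytest

from cypnet import (
    ArgumentError,
    Entity,
    FilterConfig,
    InteractionRecord,
    InteractionTable,
    SignedNetwork,
    ValidationError,
    build_network,
    filter_network,
    find_clusters,
    merge_networks,
    network_summary,
    predict_interactions,
    trace_paths,
)
from conftest import (
    make_network,
    oracle_filter,
    oracle_simple_paths,
    random_network,
)


class TestBuildNetwork:
    def test_ra_motif_projection(self, ra_table):
        net = build_network(ra_table, {"compound"}, {"regulator"})
        assert net.n_nodes == 2
        assert net.edges() == [("RA", "DAX1", 1)]

    def test_full_role_sets_keep_both_layers(self, ra_table):
        net = build_network(
            ra_table, {"compound", "regulator"}, {"regulator", "enzyme"}
        )
        assert net.n_nodes == 3 and net.n_edges == 2

    def test_empty_table_gives_empty_network(self):
        net = build_network(
            InteractionTable(), {"compound"}, {"regulator"}
        )
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_conflicting_signs_collapse_to_unknown(self):
        entities = {
            "A": Entity("A", "A", "compound"),
            "B": Entity("B", "B", "regulator"),
        }
        table = InteractionTable(
            entities=entities,
            records=[InteractionRecord("A", "B", +1), InteractionRecord("A", "B", -1)],
        )
        net = build_network(table, {"compound"}, {"regulator"})
        assert net.edges() == [("A", "B", 0)]

    def test_empty_role_set_is_an_argument_error(self, ra_table):
        with pytest.raises(ArgumentError):
            build_network(ra_table, set(), {"regulator"})


class TestFilterNetwork:
    def test_two_rules_on_small_example(self):
        nodes = {"c1": "compound", "c2": "compound",
                 "r1": "regulator", "r2": "regulator",
                 "r3": "regulator", "r4": "regulator"}
        edges = [("c1", "r1", 1), ("c1", "r2", 1), ("c1", "r3", -1),
                 ("c2", "r1", 1), ("c2", "r2", -1)]
        out = filter_network(make_network(nodes, edges),
                             FilterConfig(min_compound_edges=3))
        assert set(out.nodes()) == {"c1", "r1", "r2", "r3"}
        assert set(out.nodes()) == oracle_filter(nodes, edges, 3)

    def test_zero_threshold_without_orphan_rule_is_identity(self, ra_network):
        cfg = FilterConfig(min_compound_edges=0, drop_orphan_regulators=False)
        assert filter_network(ra_network, cfg) == ra_network

    def test_all_compounds_below_threshold_cascades_to_regulators(self):
        nodes = {"c1": "compound", "r1": "regulator"}
        out = filter_network(make_network(nodes, [("c1", "r1", 1)]),
                             FilterConfig(min_compound_edges=2))
        assert out.nodes() == []

    def test_input_network_is_not_mutated(self, ra_network):
        before = set(ra_network.nodes())
        filter_network(ra_network, FilterConfig(min_compound_edges=5))
        assert set(ra_network.nodes()) == before

    @pytest.mark.parametrize("iterate", [False, True])
    def test_matches_rule_oracle_on_random_graphs(self, iterate):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(3, 12))
            net = random_network(rng, n_nodes=n, edge_prob=0.3)
            nodes = {e.id: e.role for e in net.entities()}
            edges = net.edges()
            min_edges = int(rng.integers(0, 4))
            got = filter_network(
                net,
                FilterConfig(min_compound_edges=min_edges,
                             iterate_to_fixpoint=iterate),
            )
            assert set(got.nodes()) == oracle_filter(
                nodes, edges, min_edges, iterate=iterate
            )

    def test_fixpoint_mode_is_idempotent(self):
        rng = np.random.default_rng(7)
        cfg = FilterConfig(min_compound_edges=2, iterate_to_fixpoint=True)
        for _ in range(20):
            net = random_network(rng, n_nodes=10, edge_prob=0.25)
            once = filter_network(net, cfg)
            assert filter_network(once, cfg) == once

    def test_negative_threshold_rejected(self):
        with pytest.raises(ArgumentError):
            FilterConfig(min_compound_edges=-1)


class TestMergeNetworks:
    def test_merges_the_two_layers(self):
        cr = make_network({"RA": "compound", "DAX1": "regulator"},
                          [("RA", "DAX1", 1)])
        re = make_network({"DAX1": "regulator", "CYP19A1": "enzyme"},
                          [("DAX1", "CYP19A1", -1)])
        merged = merge_networks(cr, re)
        assert merged.n_nodes == 3
        assert set(merged.edges()) == {("RA", "DAX1", 1), ("DAX1", "CYP19A1", -1)}

    def test_merge_with_empty_is_identity(self, ra_network):
        assert merge_networks(ra_network, SignedNetwork()) == ra_network

    def test_merge_is_idempotent_commutative_associative(self):
        rng = np.random.default_rng(3)
        roles = {f"n{i:02d}": ["compound", "regulator", "enzyme"][i % 3]
                 for i in range(6)}
        for _ in range(15):
            a = random_network(rng, n_nodes=6, edge_prob=0.3, roles=roles)
            b = random_network(rng, n_nodes=6, edge_prob=0.3, roles=roles)
            c = random_network(rng, n_nodes=6, edge_prob=0.3, roles=roles)
            assert merge_networks(a, a) == a
            assert merge_networks(a, b) == merge_networks(b, a)
            assert merge_networks(merge_networks(a, b), c) == merge_networks(
                a, merge_networks(b, c)
            )

    def test_conflicting_edge_signs_collapse_to_unknown(self):
        a = make_network({"x": "compound", "y": "regulator"}, [("x", "y", 1)])
        b = make_network({"x": "compound", "y": "regulator"}, [("x", "y", -1)])
        assert merge_networks(a, b).edges() == [("x", "y", 0)]

    def test_role_conflict_is_a_validation_error(self):
        a = make_network({"x": "compound"}, [])
        b = make_network({"x": "regulator"}, [])
        with pytest.raises(ValidationError, match="conflicting roles"):
            merge_networks(a, b)


class TestFindClusters:
    def test_ranked_by_size_with_hub_tiebreak(self):
        nodes = {f"c{i}": "compound" for i in range(5)}
        nodes.update({"r1": "regulator", "r2": "regulator", "r3": "regulator"})
        edges = [(f"c{i}", "r1", 1) for i in range(5)]
        edges += [(f"c{i}", "r2", 1) for i in range(3)]
        clusters = find_clusters(make_network(nodes, edges))
        assert [(c.hub_id, c.size) for c in clusters] == [("r1", 5), ("r2", 3)]

    def test_shared_compound_belongs_to_both_clusters(self):
        nodes = {"c": "compound", "r1": "regulator", "r2": "regulator"}
        clusters = find_clusters(
            make_network(nodes, [("c", "r1", 1), ("c", "r2", -1)])
        )
        assert all(c.member_compound_ids == frozenset({"c"}) for c in clusters)
        assert len(clusters) == 2

    def test_empty_network_has_no_clusters(self):
        assert find_clusters(SignedNetwork()) == []

    def test_membership_sum_equals_compound_regulator_edge_count(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            net = random_network(rng, n_nodes=12, edge_prob=0.3)
            n_cr_edges = sum(
                1 for u, v, _ in net.edges()
                if net.role(u) == "compound" and net.role(v) == "regulator"
            )
            assert sum(c.size for c in find_clusters(net)) == n_cr_edges


class TestTracePaths:
    def test_ra_motif_path_composes_to_downregulation(self, ra_network):
        paths = trace_paths(ra_network, "RA")
        assert len(paths) == 1
        (p,) = paths
        assert p.node_sequence == ("RA", "DAX1", "CYP19A1")
        assert p.edge_signs == (1, -1)
        assert p.net_sign == -1

    def test_single_activating_edge(self):
        net = make_network({"c": "compound", "e": "enzyme"}, [("c", "e", 1)])
        (p,) = trace_paths(net, "c")
        assert p.node_sequence == ("c", "e") and p.net_sign == 1

    def test_unknown_edge_absorbs_sign(self):
        net = make_network(
            {"c": "compound", "r": "regulator", "e": "enzyme"},
            [("c", "r", 0), ("r", "e", -1)],
        )
        (p,) = trace_paths(net, "c")
        assert p.net_sign == 0

    def test_unknown_compound_raises_lookup_error(self, ra_network):
        with pytest.raises(KeyError):
            trace_paths(ra_network, "nope")

    def test_non_compound_start_is_an_argument_error(self, ra_network):
        with pytest.raises(ArgumentError):
            trace_paths(ra_network, "DAX1")

    def test_output_is_lexicographic_in_node_sequence(self):
        nodes = {"c": "compound", "a": "regulator", "b": "regulator",
                 "e": "enzyme"}
        edges = [("c", "b", 1), ("c", "a", 1), ("a", "e", 1), ("b", "e", -1)]
        seqs = [p.node_sequence for p in trace_paths(make_network(nodes, edges), "c")]
        assert seqs == sorted(seqs)

    def test_depth_cap_limits_path_length(self):
        nodes = {"c": "compound", **{f"r{i}": "regulator" for i in range(5)}}
        chain = [("c", "r0", 1)] + [(f"r{i}", f"r{i+1}", 1) for i in range(4)]
        net = make_network(nodes, chain)
        assert trace_paths(net, "c", max_depth=3) == []
        assert len(trace_paths(net, "c", max_depth=5)) == 1

    def test_matches_bruteforce_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(2024)
        for _ in range(30):
            n = int(rng.integers(3, 13))
            net = random_network(rng, n_nodes=n, edge_prob=0.3, acyclic=True)
            compounds = net.nodes_with_role("compound")
            for c in compounds:
                got = {(p.node_sequence, p.net_sign) for p in trace_paths(net, c, 12)}
                assert got == oracle_simple_paths(net, c, 12)

    def test_net_sign_equals_recomputed_sign_product(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            net = random_network(rng, n_nodes=8, edge_prob=0.35, acyclic=True)
            for c in net.nodes_with_role("compound"):
                for p in trace_paths(net, c):
                    expected = 1
                    for s in p.edge_signs:
                        expected = 0 if (s == 0 or expected == 0) else expected * s
                    assert p.net_sign == expected

    def test_cyclic_network_terminates(self):
        nodes = {"c": "compound", "r1": "regulator", "r2": "regulator",
                 "e": "enzyme"}
        edges = [("c", "r1", 1), ("r1", "r2", 1), ("r2", "r1", -1),
                 ("r2", "e", 1)]
        paths = trace_paths(make_network(nodes, edges), "c")
        assert [p.node_sequence for p in paths] == [("c", "r1", "r2", "e")]


class TestPredictInteractions:
    def test_ra_motif_predicts_single_downregulation(self, ra_network):
        table = predict_interactions(ra_network)
        assert table.to_dict("records") == [
            {
                "compound": "RA",
                "enzyme": "CYP19A1",
                "net_sign": -1,
                "n_paths": 1,
                "paths": "RA->DAX1->CYP19A1",
            }
        ]

    def test_compound_without_enzyme_path_yields_no_row(self):
        net = make_network({"c": "compound", "r": "regulator"}, [("c", "r", 1)])
        assert predict_interactions(net).empty

    def test_disagreeing_paths_aggregate_to_unknown(self):
        nodes = {"c": "compound", "r1": "regulator", "r2": "regulator",
                 "e": "enzyme"}
        edges = [("c", "r1", 1), ("r1", "e", 1), ("c", "r2", 1), ("r2", "e", -1)]
        table = predict_interactions(make_network(nodes, edges))
        assert len(table) == 1
        row = table.iloc[0]
        assert row["net_sign"] == 0 and row["n_paths"] == 2


class TestNetworkSummary:
    def test_ra_motif_counts(self, ra_network):
        assert network_summary(ra_network) == {
            "n_compounds": 1,
            "n_regulators": 1,
            "n_enzymes": 1,
            "n_nodes": 3,
            "n_edges": 2,
            "n_clusters": 1,
        }

    def test_empty_network_counts_are_zero(self):
        summary = network_summary(SignedNetwork())
        assert all(v == 0 for v in summary.values())

    def test_role_counts_sum_to_node_count(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            net = random_network(rng, n_nodes=10, edge_prob=0.3)
            s = network_summary(net)
            assert s["n_compounds"] + s["n_regulators"] + s["n_enzymes"] == s["n_nodes"]
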