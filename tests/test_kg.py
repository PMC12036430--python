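"""Knowledge-graph channel: loading, path enumeration, degree weighting."""

import io
import math

import numpy as np
import pytest

from dtifuse import (KnowledgeGraph, Path, dti_kg_score, enumerate_paths,
                     load_graph, path_weight)
from dtifuse.errors import ConfigError, ContractError, ParseError
from dtifuse.kg import score_path


class TestLoadGraph:
    def test_empty_stream_gives_empty_graph(self):
        kg = load_graph(io.StringIO(""))
        assert kg.n_nodes == 0 and kg.n_edges == 0

    def test_duplicate_rows_collapse_to_one_edge(self):
        kg = load_graph(["D1,drug,G1,gene", "D1,drug,G1,gene"])
        assert kg.n_nodes == 2 and kg.n_edges == 1
        assert kg.degree("D1") == 1 and kg.degree("G1") == 1

    def test_shipped_fixture_degree_sum(self, kg_small):
        # 6 drugs x 8 genes, 14 hand-listed edges -> sum of degrees 28
        assert kg_small.n_nodes == 14
        assert kg_small.n_edges == 14
        assert sum(kg_small.graph.degree[n] for n in kg_small.graph) == 28

    def test_source_tags_merge_on_duplicate(self):
        kg = load_graph(["D1,drug,G1,gene,dbA", "d1,drug,G1,gene,dbB"])
        assert kg.n_edges == 1
        assert kg.graph.edges["d1", "g1"]["sources"] == {"dbA", "dbB"}

    def test_malformed_row_reports_line_number(self):
        with pytest.raises(ParseError, match="line 2"):
            load_graph(["D1,drug,G1,gene", "D2,drug,G2"])

    def test_bad_kind_rejected(self):
        with pytest.raises(ParseError, match="kinds"):
            load_graph(["D1,drug,G1,protein"])

    def test_self_loop_warns_by_default_errors_when_configured(self, caplog):
        kg = load_graph(["D1,drug,D1,drug", "D1,drug,G1,gene"])
        assert kg.n_edges == 1
        with pytest.raises(ParseError, match="self-loop"):
            load_graph(["D1,drug,D1,drug"], on_self_loop="error")

    def test_lookup_is_case_insensitive_after_trim(self, kg_small):
        assert " druga " in kg_small
        assert kg_small.degree("DRUGA") == 3


class TestEnumeratePaths:
    def test_direct_edge_included(self, kg_small):
        paths, truncated = enumerate_paths(kg_small, "DrugA", "GeneA", max_hops=4)
        assert Path(("druga", "genea")) in paths
        assert not truncated

    def test_absent_node_gives_empty(self, kg_small):
        assert enumerate_paths(kg_small, "X", "GeneA")[0] == []

    def test_matches_recursive_dfs_oracle(self, oracle):
        rng = np.random.default_rng(7)
        adj = oracle.random_adjacency(rng, 12, 0.3)
        kg = oracle.adjacency_to_graph(adj)
        for max_hops in (1, 2, 3, 4):
            got, _ = enumerate_paths(kg, "N0", "N5", max_hops=max_hops)
            expect = oracle.dfs_paths(adj, "N0", "N5", max_hops)
            assert {p.nodes for p in got} == {
                tuple(n.casefold() for n in path) for path in expect}

    def test_order_is_deterministic_and_sorted(self, kg_small):
        paths, _ = enumerate_paths(kg_small, "DrugA", "GeneG", max_hops=4)
        keys = [(p.hop_count, p.nodes) for p in paths]
        assert keys == sorted(keys)
        again, _ = enumerate_paths(kg_small, "DrugA", "GeneG", max_hops=4)
        assert paths == again

    def test_path_cap_truncates_with_flag(self, oracle):
        adj = oracle.random_adjacency(np.random.default_rng(3), 12, 0.8)
        kg = oracle.adjacency_to_graph(adj)
        paths, truncated = enumerate_paths(kg, "N0", "N5", max_hops=4, path_cap=5)
        assert truncated and len(paths) == 5

    def test_bad_max_hops(self, kg_small):
        with pytest.raises(ConfigError):
            enumerate_paths(kg_small, "DrugA", "GeneA", max_hops=0)


class TestPathWeight:
    def test_two_node_graph_weight_half(self):
        kg = load_graph(["d,drug,t,gene"])
        assert path_weight(kg, Path(("d", "t"))) == pytest.approx(0.5)

    def test_three_node_chain_weight_half(self):
        kg = load_graph(["d,drug,g,gene", "g,gene,t,drug"])
        # ((1+2)/6 + (2+1)/6) / 2 = 0.5
        assert path_weight(kg, Path(("d", "g", "t"))) == pytest.approx(0.5)

    def test_matches_degree_table_recomputation(self, oracle):
        rng = np.random.default_rng(11)
        for _ in range(20):
            adj = oracle.random_adjacency(rng, int(rng.integers(4, 15)), 0.35)
            kg = oracle.adjacency_to_graph(adj)
            nodes = sorted(adj)
            for s in nodes[:3]:
                for t in nodes[-3:]:
                    for path in oracle.dfs_paths(adj, s, t, 4):
                        got = path_weight(kg, Path(tuple(n.casefold() for n in path)))
                        assert got == pytest.approx(oracle.path_weight(adj, path))

    def test_invalid_path_is_contract_violation(self, kg_small):
        with pytest.raises(ContractError):
            path_weight(kg_small, Path(("druga", "geneh")))  # not an edge
        with pytest.raises(ContractError):
            path_weight(kg_small, Path(("druga",)))


class TestDtiKgScore:
    def test_absent_endpoint_scores_zero(self, kg_small):
        ev = dti_kg_score(kg_small, "Nope", "GeneA")
        assert ev.score == 0.0 and ev.best_path is None

    def test_direct_edge_scores_exactly_one(self, kg_small):
        ev = dti_kg_score(kg_small, "DrugA", "GeneA")
        assert ev.score == 1.0
        assert ev.best_path.path.hop_count == 1

    def test_matches_bruteforce_oracle_on_random_graphs(self, oracle):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(4, 20))
            adj = oracle.random_adjacency(rng, n, float(rng.uniform(0.1, 0.5)))
            kg = oracle.adjacency_to_graph(adj)
            nodes = sorted(adj)
            d, t = nodes[0], nodes[-1]
            ev = dti_kg_score(kg, d, t)
            assert ev.score == pytest.approx(oracle.kg_score(adj, d, t), abs=1e-12)

    def test_no_path_within_hop_budget_scores_zero(self):
        # 5-hop chain: beyond the default 4-hop search
        rows = [f"n{i},{'drug' if i % 2 == 0 else 'gene'},"
                f"n{i+1},{'drug' if (i+1) % 2 == 0 else 'gene'}" for i in range(5)]
        kg = load_graph(rows)
        assert dti_kg_score(kg, "n0", "n5", max_hops=4).score == 0.0
        assert dti_kg_score(kg, "n0", "n5", max_hops=5).score > 0.0

    def test_reason_names_best_path(self, kg_small):
        ev = dti_kg_score(kg_small, "DrugA", "GeneD")
        assert "Found" in ev.reason and "paths between DrugA and GeneD" in ev.reason
        route = " → ".join(kg_small.label(n) for n in ev.best_path.path.nodes)
        assert route in ev.reason

    def test_symmetry(self, oracle):
        rng = np.random.default_rng(5)
        for _ in range(10):
            adj = oracle.random_adjacency(rng, 12, 0.3)
            kg = oracle.adjacency_to_graph(adj)
            assert (dti_kg_score(kg, "N1", "N8").score
                    == pytest.approx(dti_kg_score(kg, "N8", "N1").score))

    def test_hop_discount_strictly_decreasing_at_equal_weight(self, kg_small):
        # same weight, more hops -> strictly smaller combined score
        from dtifuse.kg import combined_score
        assert combined_score(0.4, 2) > combined_score(0.4, 3)
        # and scored paths respect the discount
        ev = dti_kg_score(kg_small, "DrugA", "GeneG")
        for ps in ev.all_paths:
            assert ps.combined_score == pytest.approx(
                min(1.0, ps.weight / math.log(1 + ps.path.hop_count)))

    def test_truncated_enumeration_flagged(self, oracle):
        adj = oracle.random_adjacency(np.random.default_rng(3), 14, 0.8)
        kg = oracle.adjacency_to_graph(adj)
        ev = dti_kg_score(kg, "N0", "N9", path_cap=10)
        assert ev.truncated
        assert "+" in ev.reason.splitlines()[0]

    def test_score_path_consistency(self, kg_small):
        paths, _ = enumerate_paths(kg_small, "DrugB", "GeneE")
        for p in paths:
            ps = score_path(kg_small, p)
            assert 0.0 < ps.weight < 1.0
            assert 0.0 <= ps.combined_score <= 1.0
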