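"""Coordinator workflow: format contracts, per-pair runs, batching, CSV."""

import csv

import pytest

from dtifuse import (Batch, FixtureSpec, QueryPair, RunConfig,
                     make_search_fixture, run_batch, run_pair,
                     validate_agent_output)
from dtifuse.errors import ConfigError, ContractError, FormatError
from dtifuse.orchestrator import CSV_HEADER

# Ten pinned malformed payloads: (payload, schema)
NEGATIVE_CASES = [
    (["D", "T"], "triple"),                        # wrong arity (short)
    (["D", "T", 0.5, 0.5], "triple"),              # wrong arity (long)
    (["D", "T", "high"], "triple"),                # wrong type for score
    (["D", "T", 1.2], "triple"),                   # score above 1
    (["D", "T", -0.1], "triple"),                  # score below 0
    (["D", "T", float("nan")], "triple"),          # non-finite score
    ([42, "T", 0.5], "triple"),                    # wrong type for name
    (["D", "T", 0.1, 0.2, 0.3, 0.5], "seven_field"),     # missing reasoning
    (["D", "T", 0.1, 2.0, 0.3, 0.5, "ok"], "seven_field"),  # channel out of range
    (["D", "T", 0.1, 0.2, 0.3, 0.5, ""], "seven_field"),    # empty reasoning
]


class TestFormatContracts:
    def test_valid_triple_passes_unchanged(self):
        assert validate_agent_output(["D", "T", 0.5], "triple") == ["D", "T", 0.5]

    def test_valid_seven_field_with_absence_markers(self):
        payload = ["D", "T", "", 0.4, "", 0.4, "only graph evidence"]
        assert validate_agent_output(payload, "seven_field") == payload

    @pytest.mark.parametrize("payload,schema", NEGATIVE_CASES)
    def test_malformed_payload_raises_format_error(self, payload, schema):
        with pytest.raises(FormatError):
            validate_agent_output(payload, schema)

    def test_error_names_offending_position(self):
        with pytest.raises(FormatError, match="position 3"):
            validate_agent_output(["D", "T", "high"], "triple")

    def test_boolean_is_not_a_score(self):
        with pytest.raises(FormatError):
            validate_agent_output(["D", "T", True], "triple")

    def test_unknown_schema(self):
        with pytest.raises(ConfigError):
            validate_agent_output(["D", "T", 0.5], "pair")


def _fixture_cfg(tmp_path, **kw):
    """Config over small generated fixtures: lookup AI + fixture search + KG."""
    spec = FixtureSpec(
        seed=9, n_drugs=8, n_genes=10, edge_density=0.3,
        planted_pairs=[("AlphaDrug", "BetaGene", "direct"),
                       ("GammaDrug", "DeltaGene", "k_hop:3"),
                       ("EpsDrug", "ZetaGene", "none")],
        search_profile=(10, 2, 0), search_n=10)  # T=12 -> D=0.4
    from dtifuse import write_fixture_dir
    paths = write_fixture_dir(spec, str(tmp_path / "fx"))
    return RunConfig(kg_edges=paths["edges"], search_fixture=paths["search"],
                     ai_backend="lookup", ai_lookup=paths["lookup"], **kw), spec


class TestRunPair:
    def test_worked_example_reproduces_final_score(self, worked_example_config,
                                                   worked_example):
        rec, trace = run_pair(
            QueryPair(drug=worked_example.drug, target=worked_example.target),
            worked_example_config)
        assert rec.final_score == worked_example.expected_final == 0.34045
        assert rec.ai_score == worked_example.ai_score
        assert rec.kg_score == worked_example.kg_score
        assert rec.search_score == worked_example.search_score

    def test_ablate_kg_means_remaining_two(self, worked_example):
        ex = worked_example
        cfg = RunConfig(ablate={"kg"}, ai_backend="lookup",
                        ai_lookup={(ex.drug, ex.target): 0.2},
                        search_fixture=_search_fixture_with_d(ex, 0.4))
        rec, _ = run_pair(QueryPair(drug=ex.drug, target=ex.target), cfg)
        assert rec.search_score == 0.4
        assert rec.final_score == pytest.approx(0.3)
        assert rec.kg_score is None

    def test_all_channels_ablated_is_config_error(self):
        cfg = RunConfig(ablate={"ai", "kg", "search"})
        with pytest.raises(ConfigError):
            run_pair(QueryPair(drug="D", target="T"), cfg)

    def test_override_hook_refused_in_normal_mode(self):
        with pytest.raises(ConfigError, match="override"):
            RunConfig(kg_score_override={("D", "T"): 0.5})

    def test_failed_channel_skipped_by_default(self, tmp_path):
        cfg, _ = _fixture_cfg(tmp_path)
        # pair unknown to the lookup table: AI channel fails, KG+Search carry on
        rec, _ = run_pair(QueryPair(drug="AlphaDrug", target="DeltaGene"), cfg)
        assert rec.ai_score is None
        assert rec.final_score is not None

    def test_failed_channel_aborts_under_fail_policy(self, tmp_path):
        cfg, _ = _fixture_cfg(tmp_path, failure_policy="fail")
        from dtifuse.errors import DtifuseError
        with pytest.raises(DtifuseError):
            run_pair(QueryPair(drug="AlphaDrug", target="DeltaGene"), cfg)

    def test_empty_names_rejected(self):
        with pytest.raises(ContractError):
            QueryPair(drug=" ", target="T")


def _search_fixture_with_d(ex, d_value):
    # plant indicator counts so that T = D * 30 exactly
    t = int(round(d_value * 30))
    profile = (min(t, 10), min(max(t - 10, 0), 10), max(t - 20, 0))
    spec = FixtureSpec(planted_pairs=[(ex.drug, ex.target, "none")],
                       search_profile=profile, search_n=10)
    return make_search_fixture(spec)


class TestRunBatch:
    def test_empty_batch_writes_header_only(self, tmp_path):
        cfg, _ = _fixture_cfg(tmp_path)
        out = tmp_path / "out.csv"
        run_batch(Batch(pairs=[]), cfg, out_csv=str(out))
        lines = out.read_text().splitlines()
        assert len(lines) == 1
        assert lines[0].replace('"', "").split(",") == CSV_HEADER

    def test_chunking_arithmetic_25_pairs(self, tmp_path):
        cfg, spec = _fixture_cfg(tmp_path)
        pairs = [QueryPair(drug=d, target=t)
                 for d, t, _ in spec.planted_pairs] * 9  # 27 -> trim to 25
        batch = Batch(pairs=pairs[:25], batch_size=10)
        assert [len(c) for c in batch.chunks()] == [10, 10, 5]
        records = run_batch(batch, cfg)
        assert len(records) == 25
        assert [r.drug for r in records] == [p.drug for p in batch.pairs]

    def test_row_count_equals_pair_count_even_with_failures(self, tmp_path):
        # AI-only run whose lookup table misses every pair: all pairs fail,
        # but each still produces an error row instead of aborting the batch
        cfg, spec = _fixture_cfg(tmp_path, ablate={"kg", "search"})
        pairs = [QueryPair(drug="NotInLookup", target=f"X{i}") for i in range(3)]
        pairs += [QueryPair(drug=d, target=t) for d, t, _ in spec.planted_pairs]
        out = tmp_path / "out.csv"
        records = run_batch(Batch(pairs=pairs), cfg, out_csv=str(out))
        assert len(records) == len(pairs)
        with open(out, newline="") as fh:
            rows = list(csv.DictReader(fh))
        assert len(rows) == len(pairs)
        assert rows[0]["final_score"] == ""
        assert rows[0]["reasoning"].startswith("ERROR")
        assert rows[-1]["final_score"] != ""

    def test_unwritable_output_fails_before_processing(self, tmp_path):
        cfg, spec = _fixture_cfg(tmp_path)
        with pytest.raises(OSError):
            run_batch(Batch(pairs=[]), cfg, out_csv=str(tmp_path / "no" / "out.csv"))

    def test_two_runs_byte_identical(self, tmp_path):
        cfg, spec = _fixture_cfg(tmp_path)
        pairs = [QueryPair(drug=d, target=t) for d, t, _ in spec.planted_pairs]
        out1, out2 = tmp_path / "a.csv", tmp_path / "b.csv"
        run_batch(Batch(pairs=pairs), cfg, out_csv=str(out1))
        run_batch(Batch(pairs=pairs), cfg, out_csv=str(out2))
        assert out1.read_bytes() == out2.read_bytes()

    def test_trace_sidecar_written(self, tmp_path):
        cfg, spec = _fixture_cfg(tmp_path)
        d, t, _ = spec.planted_pairs[0]
        run_batch(Batch(pairs=[QueryPair(drug=d, target=t)]), cfg,
                  trace_dir=str(tmp_path / "traces"))
        trace_file = tmp_path / "traces" / f"{d}_{t}.txt"
        assert trace_file.exists()
        assert "CALCULATE_SCORES" in trace_file.read_text()
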