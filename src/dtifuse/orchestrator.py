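"""Coordinator: per-pair workflow, format contracts, batching, CSV output.

Every channel hands its result back as the triple ``[drug, target, score]``
and the fused result as the seven-field list
``[drug, target, ai, kg, search, final, reasoning]``; both payloads are
validated against their contract, and any deviation raises a typed
:class:`~dtifuse.errors.FormatError`.  Batches are processed in consecutive
chunks of ``batch_size`` pairs (the "superposition" submission pattern);
with the default ``skip`` policy a failing channel is dropped from the
fusion and a fully failing pair becomes an error row, never an aborted
batch.
"""

from __future__ import annotations

import csv
import logging
import math
import os
from dataclasses import dataclass
from typing import Iterable

from . import backends as be
from . import kg as kgmod
from . import search as se
from .aggregation import (ABSENT, EvidenceBundle, PredictionRecord,
                          ReasoningTrace, aggregate, to_output_list)
from .config import RunConfig
from .errors import (ConfigError, ContractError, DtifuseError, FormatError,
                     PairError)

logger = logging.getLogger(__name__)

CSV_HEADER = ["drug", "target", "ai_score", "kg_score", "search_score",
              "final_score", "reasoning"]


@dataclass(frozen=True)
class QueryPair:
    drug: str
    target: str

    def __post_init__(self):
        if not self.drug.strip() or not self.target.strip():
            raise ContractError("drug and target names must be non-empty")


@dataclass
class Batch:
    pairs: list[QueryPair]
    batch_size: int = 10

    def chunks(self) -> Iterable[list[QueryPair]]:
        for i in range(0, len(self.pairs), self.batch_size):
            yield self.pairs[i:i + self.batch_size]


# ---------------------------------------------------------------------------
# Format contracts


def _check_name(value, pos: int):
    if not isinstance(value, str) or not value.strip():
        raise FormatError(f"expected non-empty string, got {value!r}", position=pos)


def _check_score(value, pos: int, allow_absent: bool = False):
    if allow_absent and value == ABSENT:
        return
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise FormatError(f"expected a number, got {value!r}", position=pos)
    if not math.isfinite(value):
        raise FormatError(f"score must be finite, got {value!r}", position=pos)
    if not (0.0 <= value <= 1.0):
        raise FormatError(f"score {value!r} outside [0, 1]", position=pos)


def validate_agent_output(payload: list, schema: str) -> list:
    """Enforce an inter-agent format contract; return the payload unchanged.

    ``schema`` is ``"triple"`` ([drug, target, score]) or ``"seven_field"``
    ([drug, target, ai, kg, search, final, reasoning], where the three
    channel scores may be the empty-string absence marker).
    """
    if schema == "triple":
        if not isinstance(payload, (list, tuple)) or len(payload) != 3:
            raise FormatError(f"triple must have 3 elements, got "
                              f"{len(payload) if isinstance(payload, (list, tuple)) else type(payload).__name__}")
        _check_name(payload[0], 1)
        _check_name(payload[1], 2)
        _check_score(payload[2], 3)
        return list(payload)
    if schema == "seven_field":
        if not isinstance(payload, (list, tuple)) or len(payload) != 7:
            raise FormatError(f"seven-field list must have 7 elements, got "
                              f"{len(payload) if isinstance(payload, (list, tuple)) else type(payload).__name__}")
        _check_name(payload[0], 1)
        _check_name(payload[1], 2)
        for pos in (3, 4, 5):
            _check_score(payload[pos - 1], pos, allow_absent=True)
        _check_score(payload[5], 6)
        if not isinstance(payload[6], str) or not payload[6]:
            raise FormatError("reasoning must be a non-empty string", position=7)
        return list(payload)
    raise ConfigError(f"unknown schema {schema!r}")


# ---------------------------------------------------------------------------
# Channel runners


class _Runtime:
    """Backends and data loaded once per run and shared across pairs."""

    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self.graph: kgmod.KnowledgeGraph | None = None
        if "kg" in cfg.enabled_channels() and cfg.kg_edges is not None:
            self.graph = kgmod.load_graph(cfg.kg_edges)
        self.predictor: be.PredictorBackend | None = None
        if "ai" in cfg.enabled_channels():
            self.predictor = be.get_predictor_backend(
                cfg.ai_backend, seed=cfg.ai_seed, lookup=cfg.ai_lookup)
        self.searcher: se.SearchBackend | None = None
        if "search" in cfg.enabled_channels():
            if cfg.search_backend == "fixture":
                self.searcher = se.FixtureSearchBackend(cfg.search_fixture or {})
            elif cfg.search_backend == "live":
                self.searcher = se.LiveSearchBackend(cfg.search_endpoint)
            else:
                raise ConfigError(f"unknown search backend {cfg.search_backend!r}")
        self.text_backend = be.get_text_backend(cfg.llm_backend)
        self.override = {
            (d.strip().casefold(), t.strip().casefold()): s
            for (d, t), s in (cfg.kg_score_override or {}).items()
        }

    def ai_channel(self, pair: QueryPair) -> be.AiEvidence:
        ev = be.predict_interaction(
            be.PredictorInput(drug_name=pair.drug, target_name=pair.target),
            self.predictor)
        validate_agent_output([ev.drug, ev.target, ev.score], "triple")
        return ev

    def kg_channel(self, pair: QueryPair) -> kgmod.KgEvidence:
        key = (pair.drug.strip().casefold(), pair.target.strip().casefold())
        if key in self.override:
            ev = kgmod.KgEvidence(
                drug=pair.drug, target=pair.target, score=self.override[key],
                best_path=None, all_paths=[],
                reason="Graph score pinned by override hook.")
        else:
            if self.graph is None:
                raise ConfigError("kg channel enabled but no edge list configured")
            ev = kgmod.dti_kg_score(self.graph, pair.drug, pair.target,
                                    max_hops=self.cfg.max_hops,
                                    path_cap=self.cfg.path_cap)
        validate_agent_output([ev.drug, ev.target, ev.score], "triple")
        return ev

    def search_channel(self, pair: QueryPair) -> se.SearchEvidence:
        query = se.build_query(pair.drug, pair.target)
        results = se.fetch_results(query, self.searcher, n=self.cfg.search_n)
        ev = se.score_search(results, pair.drug, pair.target,
                             positive_keywords=self.cfg.positive_keywords,
                             strong_keywords=self.cfg.strong_keywords,
                             text_backend=self.text_backend)
        validate_agent_output([ev.drug, ev.target, ev.score], "triple")
        return ev


def run_pair(pair: QueryPair, cfg: RunConfig,
             runtime: _Runtime | None = None,
             ) -> tuple[PredictionRecord, ReasoningTrace]:
    """Run all enabled channels for one pair, fuse, and validate the output."""
    if not cfg.enabled_channels():
        raise ConfigError("all evidence channels are ablated; nothing to run")
    rt = runtime or _Runtime(cfg)
    bundle = EvidenceBundle(drug=pair.drug, target=pair.target)
    runners = {"ai": rt.ai_channel, "kg": rt.kg_channel, "search": rt.search_channel}
    for channel in cfg.enabled_channels():
        try:
            setattr(bundle, channel, runners[channel](pair))
        except DtifuseError as exc:
            if cfg.failure_policy == "fail":
                raise
            logger.error("channel %s failed for %s-%s: %s; treating as absent",
                         channel, pair.drug, pair.target, exc)
    if not bundle.present():
        raise PairError(f"every channel failed for {pair.drug}-{pair.target}")
    record, trace = aggregate(bundle, text_backend=rt.text_backend,
                              weights=cfg.weights or None)
    validate_agent_output(to_output_list(record), "seven_field")
    return record, trace


def run_batch(batch: Batch, cfg: RunConfig, out_csv: str | None = None,
              trace_dir: str | None = None) -> list[PredictionRecord]:
    """Process pairs in consecutive chunks and optionally write a CSV.

    One output row per input pair, in input order; a pair whose every
    channel fails yields a row with empty scores and an error note rather
    than aborting the batch (unless ``failure_policy`` is ``fail``).
    """
    if out_csv is not None:
        _check_writable(out_csv)
    rt = _Runtime(cfg)
    records: list[PredictionRecord] = []
    for i, chunk in enumerate(batch.chunks(), start=1):
        logger.info("processing chunk %d (%d pairs)", i, len(chunk))
        for pair in chunk:
            try:
                record, trace = run_pair(pair, cfg, runtime=rt)
            except DtifuseError as exc:
                if cfg.failure_policy == "fail":
                    raise
                logger.error("pair %s-%s failed: %s", pair.drug, pair.target, exc)
                record = PredictionRecord(
                    drug=pair.drug, target=pair.target, ai_score=None,
                    kg_score=None, search_score=None, final_score=None,
                    reasoning=f"ERROR: {exc}")
                trace = None
            records.append(record)
            if trace_dir is not None and trace is not None:
                _write_trace(trace_dir, pair, trace)
    if out_csv is not None:
        write_csv(records, out_csv)
    return records


def write_csv(records: list[PredictionRecord], path: str) -> None:
    """Seven-column CSV, one row per record; reasoning text is quoted."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_NONNUMERIC, lineterminator="\n")
        writer.writerow(CSV_HEADER)
        for rec in records:
            row = to_output_list(rec)
            if rec.final_score is None:  # failed pair: empty final column
                row[5] = ABSENT
            writer.writerow(row)
    logger.info("wrote %d rows to %s", len(records), path)


def read_pairs(path: str) -> list[QueryPair]:
    """Read a pairs CSV (``drug,target``; header optional)."""
    pairs = []
    with open(path, encoding="utf-8", newline="") as fh:
        for i, row in enumerate(csv.reader(fh), start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if i == 1 and [c.strip().lower() for c in row[:2]] == ["drug", "target"]:
                continue
            if len(row) < 2:
                raise ContractError(f"pairs file line {i}: expected drug,target")
            pairs.append(QueryPair(drug=row[0].strip(), target=row[1].strip()))
    return pairs


def _check_writable(path: str) -> None:
    directory = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(directory):
        raise OSError(f"output directory does not exist: {directory}")
    if not os.access(directory, os.W_OK):
        raise OSError(f"output directory not writable: {directory}")


def _write_trace(trace_dir: str, pair: QueryPair, trace: ReasoningTrace) -> None:
    os.makedirs(trace_dir, exist_ok=True)
    safe = f"{pair.drug}_{pair.target}".replace("/", "_").replace(" ", "_")
    with open(os.path.join(trace_dir, f"{safe}.txt"), "w", encoding="utf-8") as fh:
        fh.write(trace.render() + "\n")
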