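"""Evidence fusion with an explained reasoning trace.

The final score for a pair is the mean of the evidence channels that are
present (ML, knowledge graph, literature search), rounded to five decimals.
When a channel is ablated or failed, the mean is taken over the remaining
channels.  Per-channel weights are supported (default all 1, i.e. the plain
unweighted mean).  Alongside the numeric record, a Thought -> Action ->
Observation trace documents the analysis, the mechanistic path evidence
when the graph channel found one, and the exact arithmetic performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal

from .backends import AiEvidence, TextBackend, TemplateTextBackend, generate_text
from .errors import ContractError, FormatError
from .kg import KgEvidence
from .search import SearchEvidence

logger = logging.getLogger(__name__)

CHANNEL_LABELS = {"ai": "ML", "kg": "KG", "search": "Search"}
FINAL_DECIMALS = 5


@dataclass
class EvidenceBundle:
    """Per-pair evidence; any channel may be absent (ablation or failure)."""

    drug: str
    target: str
    ai: AiEvidence | None = None
    kg: KgEvidence | None = None
    search: SearchEvidence | None = None

    def present(self) -> list[tuple[str, float, str]]:
        """(channel key, score, reason) for each present channel, fixed order."""
        out = []
        if self.ai is not None:
            out.append(("ai", self.ai.score, self.ai.reason))
        if self.kg is not None:
            out.append(("kg", self.kg.score, self.kg.reason))
        if self.search is not None:
            out.append(("search", self.search.score, self.search.summary))
        return out


@dataclass
class TraceStep:
    phase: str  # Thought | Action | Observation
    text: str


@dataclass
class ReasoningTrace:
    steps: list[TraceStep]

    def render(self) -> str:
        return "\n".join(f"{s.phase}: {s.text}" for s in self.steps)


@dataclass
class PredictionRecord:
    """The seven-field output record for one drug-target pair."""

    drug: str
    target: str
    ai_score: float | None
    kg_score: float | None
    search_score: float | None
    final_score: float | None  # None only for a failed pair in batch output
    reasoning: str


def round_final(x: float) -> float:
    """Five-decimal rounding of the fused score, half to even."""
    return float(Decimal(x).quantize(Decimal(10) ** -FINAL_DECIMALS,
                                     rounding=ROUND_HALF_EVEN))


def aggregate(bundle: EvidenceBundle,
              text_backend: TextBackend | None = None,
              weights: dict[str, float] | None = None,
              ) -> tuple[PredictionRecord, ReasoningTrace]:
    """Fuse the present channels into a final score plus a reasoning trace.

    ``weights`` maps channel keys (``ai``/``kg``/``search``) to non-negative
    weights; absent channels are simply left out of the (weighted) mean.
    """
    channels = bundle.present()
    if not channels:
        raise ContractError(
            f"no evidence channels present for {bundle.drug}-{bundle.target}")
    for key, score, _ in channels:
        if not (0.0 <= score <= 1.0):
            raise ContractError(f"channel {key!r} score {score!r} outside [0, 1]")

    weights = weights or {}
    wts = [float(weights.get(key, 1.0)) for key, _, _ in channels]
    if any(w < 0 for w in wts) or sum(wts) == 0:
        raise ContractError(f"invalid channel weights {weights!r}")
    scores = [s for _, s, _ in channels]
    final = round_final(sum(w * s for w, s in zip(wts, scores)) / sum(wts))

    backend = text_backend or TemplateTextBackend()
    labeled = [(CHANNEL_LABELS[k], s) for k, s, _ in channels]
    reasoning = generate_text(
        {"kind": "reasoning", "drug": bundle.drug, "target": bundle.target,
         "channels": labeled, "final": final},
        backend)

    trace = _build_trace(bundle, channels, wts, final)
    record = PredictionRecord(
        drug=bundle.drug, target=bundle.target,
        ai_score=bundle.ai.score if bundle.ai else None,
        kg_score=bundle.kg.score if bundle.kg else None,
        search_score=bundle.search.score if bundle.search else None,
        final_score=final, reasoning=reasoning)
    logger.info("fused %s-%s -> %g (%d channels)",
                bundle.drug, bundle.target, final, len(channels))
    return record, trace


def _build_trace(bundle: EvidenceBundle, channels, wts, final) -> ReasoningTrace:
    steps = [TraceStep("Thought",
                       f"Analyze {', '.join(CHANNEL_LABELS[k] for k, _, _ in channels)} "
                       f"evidence for {bundle.drug}-{bundle.target} interaction.")]
    steps.append(TraceStep("Action", "ANALYZE_EVIDENCE"))
    steps.append(TraceStep("Observation", ", ".join(
        f"{CHANNEL_LABELS[k]} = {s:g}" for k, s, _ in channels)))

    # Mechanistic step only when the graph channel actually found a route.
    if bundle.kg is not None and bundle.kg.best_path is not None:
        bp = bundle.kg.best_path
        hops = bp.path.hop_count
        inner = list(bp.path.nodes[1:-1])
        via = f" via {', '.join(inner)}" if inner else " (direct edge)"
        steps.append(TraceStep("Action", "EVALUATE_MECHANISMS"))
        steps.append(TraceStep("Observation",
                               f"KG shows {hops}-hop connection{via}."))

    steps.append(TraceStep("Action", "CALCULATE_SCORES"))
    steps.append(TraceStep("Observation", _arithmetic_line(channels, wts, final)))
    return ReasoningTrace(steps=steps)


def _arithmetic_line(channels, wts, final) -> str:
    scores = [s for _, s, _ in channels]
    if all(w == wts[0] for w in wts):
        expr = " + ".join(repr(s) for s in scores)
        return f"Final Score = ({expr}) / {len(scores)} = {final:g}"
    num = " + ".join(f"{w:g}*{s!r}" for w, s in zip(wts, scores))
    return f"Final Score = ({num}) / {sum(wts):g} = {final:g}"


# ---------------------------------------------------------------------------
# Seven-field list form

ABSENT = ""  # marker for an ablated/failed channel score in the list form


def to_output_list(rec: PredictionRecord) -> list:
    """Render the record as the seven-element list contract:

    [drug, target, ai_score, kg_score, search_score, final_score, reasoning]
    with absent channel scores as the empty string.
    """
    def cell(x: float | None):
        return ABSENT if x is None else x

    return [rec.drug, rec.target, cell(rec.ai_score), cell(rec.kg_score),
            cell(rec.search_score), rec.final_score, rec.reasoning]


def from_output_list(payload: list) -> PredictionRecord:
    """Inverse of :func:`to_output_list`; validates shape on the way in."""
    if len(payload) != 7:
        raise FormatError(f"expected 7 elements, got {len(payload)}")

    def score(x, pos):
        if x == ABSENT:
            return None
        if isinstance(x, bool) or not isinstance(x, (int, float)):
            raise FormatError(f"expected number or '', got {x!r}", position=pos)
        return float(x)

    return PredictionRecord(
        drug=payload[0], target=payload[1],
        ai_score=score(payload[2], 3), kg_score=score(payload[3], 4),
        search_score=score(payload[4], 5),
        final_score=float(payload[5]), reasoning=payload[6])
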