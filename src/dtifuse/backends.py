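"""Pluggable evidence backends.

Two backend families live here: *predictors* (the ML channel, a binding
classifier emitting a probability-like score in [0, 1]) and *text
generators* (summaries and reasoning prose).  Each family has a
deterministic offline default — a seeded name-keyed mock predictor and a
slot-filling template renderer — so the whole pipeline runs with no network
and no model weights.  Structure-aware predictors consume a SMILES string
and an amino-acid sequence; the mock and lookup predictors need only names.
"""

from __future__ import annotations

import csv
import hashlib
import logging
from dataclasses import dataclass

from .errors import BackendError, InputError

logger = logging.getLogger(__name__)

#: Fixed explanation attached to every ML-channel prediction.
AI_REASON = "This agent used an ML model"


@dataclass
class PredictorInput:
    drug_name: str
    target_name: str
    smiles: str | None = None
    sequence: str | None = None


@dataclass
class AiEvidence:
    drug: str
    target: str
    score: float
    reason: str = AI_REASON


class PredictorBackend:
    """Interface: map a :class:`PredictorInput` to a score in [0, 1]."""

    name = "abstract"

    def predict(self, inp: PredictorInput) -> float:  # pragma: no cover
        raise NotImplementedError


class MockPredictor(PredictorBackend):
    """Pure function of (seed, drug name, target name) -> uniform [0, 1).

    Uses SHA-256 so the value is stable across processes and platforms;
    names are matched case-insensitively after trimming.
    """

    name = "mock"

    def __init__(self, seed: int = 0):
        self.seed = seed

    def predict(self, inp: PredictorInput) -> float:
        key = f"{self.seed}|{inp.drug_name.strip().casefold()}|{inp.target_name.strip().casefold()}"
        digest = hashlib.sha256(key.encode("utf-8")).digest()
        return int.from_bytes(digest[:8], "big") / 2**64


class LookupPredictor(PredictorBackend):
    """Scores from a user-supplied (drug, target) -> score table.

    Accepts a dict or a CSV file with columns ``drug,target,score``.
    """

    name = "lookup"

    def __init__(self, table: dict[tuple[str, str], float] | str):
        if isinstance(table, str):
            table = _read_lookup_csv(table)
        self.table = {
            (d.strip().casefold(), t.strip().casefold()): float(s)
            for (d, t), s in table.items()
        }

    def predict(self, inp: PredictorInput) -> float:
        key = (inp.drug_name.strip().casefold(), inp.target_name.strip().casefold())
        if key not in self.table:
            raise BackendError(
                f"no lookup entry for pair ({inp.drug_name!r}, {inp.target_name!r})")
        return self.table[key]


def _read_lookup_csv(path: str) -> dict[tuple[str, str], float]:
    table: dict[tuple[str, str], float] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].strip().lower() == "drug":
                continue
            d, t, s = row[0], row[1], float(row[2])
            table[(d, t)] = s
    return table


class DeepPurposePredictor(PredictorBackend):
    """Adapter for a pre-trained structure-based binding classifier.

    Wraps the DeepPurpose MPNN_CNN BindingDB binary model; the model's
    probability-like output is passed through unchanged.  Requires the
    optional ``DeepPurpose`` dependency and both a SMILES string and a
    protein sequence per query.
    """

    name = "deeppurpose"

    def __init__(self, model_name: str = "MPNN_CNN_BindingDB"):
        try:
            from DeepPurpose import DTI as dp_dti  # noqa: N813
        except ImportError as exc:
            raise BackendError(
                "DeepPurpose is not installed; install the optional "
                "dependency or select the mock/lookup backend") from exc
        self._model = dp_dti.model_pretrained(model=model_name)

    def predict(self, inp: PredictorInput) -> float:
        if not inp.smiles or not inp.sequence:
            raise InputError(
                "structure backend requires both SMILES and protein sequence")
        from DeepPurpose import utils as dp_utils
        data = dp_utils.data_process(
            X_drug=[inp.smiles], X_target=[inp.sequence], y=[0],
            drug_encoding="MPNN", target_encoding="CNN",
            split_method="no_split")
        return float(self._model.predict(data)[0])


def predict_interaction(inp: PredictorInput, backend: PredictorBackend) -> AiEvidence:
    """Run the ML channel and package the score with its fixed reason."""
    score = float(backend.predict(inp))
    if not (0.0 <= score <= 1.0) or score != score:
        raise BackendError(
            f"predictor backend {backend.name!r} returned out-of-range score {score!r}")
    logger.info("AI channel %s-%s: %g (%s backend)",
                inp.drug_name, inp.target_name, score, backend.name)
    return AiEvidence(drug=inp.drug_name, target=inp.target_name, score=score)


# ---------------------------------------------------------------------------
# Text generation


class TextBackend:
    """Interface: render a structured request (a dict of slots) to prose."""

    name = "abstract"

    def generate(self, request: dict) -> str:  # pragma: no cover
        raise NotImplementedError


class TemplateTextBackend(TextBackend):
    """Deterministic slot-filling renderer; the offline default.

    Understands two request kinds: ``summary`` (search-result digests) and
    ``reasoning`` (channel-agreement prose for the final record).  Unknown
    kinds render as a sorted key-value digest so new callers still get a
    stable, non-empty string.
    """

    name = "template"

    def generate(self, request: dict) -> str:
        kind = request.get("kind")
        if kind == "summary":
            return self._summary(request)
        if kind == "reasoning":
            return self._reasoning(request)
        body = "; ".join(f"{k}={request[k]}" for k in sorted(request) if k != "kind")
        return f"[{kind}] {body}"

    @staticmethod
    def _summary(req: dict) -> str:
        drug, target = req["drug"], req["target"]
        n = req["n_results"]
        if n == 0:
            return f"No search results for {drug}-{target}."
        parts = [f"{n} search results for {drug}-{target}."]
        if req.get("keywords_found"):
            parts.append("Keywords found: " + ", ".join(req["keywords_found"]) + ".")
        else:
            parts.append("No interaction keywords found.")
        titles = [t for t in req.get("top_titles", []) if t]
        if titles:
            parts.append("Top results: " + " | ".join(titles) + ".")
        return " ".join(parts)

    @staticmethod
    def _reasoning(req: dict) -> str:
        drug, target = req["drug"], req["target"]
        channels: list[tuple[str, float]] = req["channels"]  # (label, score)
        rendered = ", ".join(f"{label} score {score:g}" for label, score in channels)
        scores = [s for _, s in channels]
        spread = max(scores) - min(scores) if scores else 0.0
        agreement = ("channels agree" if spread <= 0.2
                     else "channels partially agree" if spread <= 0.5
                     else "channels disagree")
        verdict = ("strong" if req["final"] >= 0.7
                   else "moderate" if req["final"] >= 0.3 else "weak")
        return (f"{rendered}; {agreement}; combined evidence suggests a "
                f"{verdict} {drug}-{target} interaction (final {req['final']:g}).")


class LiveTextBackend(TextBackend):
    """Pass-through to an external chat-completion API; never used offline.

    The vendor label (e.g. the model name) is configuration; the request is
    serialized into a single prompt.  Requires an API key in the environment.
    """

    name = "live"

    def __init__(self, label: str, api_key_env: str = "DTIFUSE_LLM_API_KEY"):
        import os
        self.label = label
        self.api_key = os.environ.get(api_key_env)
        if not self.api_key:
            raise BackendError(
                f"live text backend {label!r} selected but {api_key_env} is unset")

    def generate(self, request: dict) -> str:
        raise BackendError(
            f"live text backend {self.label!r} has no transport in this build; "
            "use the template backend")


def generate_text(request: dict, backend: TextBackend) -> str:
    out = backend.generate(request)
    if not out:
        raise BackendError(f"text backend {backend.name!r} returned empty output")
    return out


def get_predictor_backend(name: str, *, seed: int = 0,
                          lookup: dict | str | None = None) -> PredictorBackend:
    if name == "mock":
        return MockPredictor(seed=seed)
    if name == "lookup":
        if lookup is None:
            raise BackendError("lookup backend selected but no lookup table given")
        return LookupPredictor(lookup)
    if name == "deeppurpose":
        return DeepPurposePredictor()
    raise BackendError(f"unknown predictor backend {name!r}")


def get_text_backend(name: str) -> TextBackend:
    if name == "template":
        return TemplateTextBackend()
    if name.startswith("live:"):
        return LiveTextBackend(label=name.split(":", 1)[1])
    raise BackendError(f"unknown text backend {name!r}")
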