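"""Literature-search evidence channel.

Each search result r_i is scored by three binary indicators over its text
(title plus content, case-insensitive substring match):

    S(r_i) = I(both names present) + I(any positive keyword) + I(any strong keyword)

so S(r_i) in {0, 1, 2, 3}.  Over n results, T = sum S(r_i), the maximum is
M = 3n, and the channel score is D = round(T/M, 2) (round half to even), or
0 when there are no results.  Scoring is pure text arithmetic, independent
of the summary backend and of result order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal

from .backends import TextBackend, TemplateTextBackend, generate_text
from .errors import BackendError, ContractError, RetrievalError

logger = logging.getLogger(__name__)

#: Interaction-verb keywords (any one sets the positive indicator).
DEFAULT_POSITIVE_KEYWORDS = ("interacts", "binds", "activates", "modulates")
#: Effect-strength keywords (any one sets the strong indicator).
DEFAULT_STRONG_KEYWORDS = ("strong", "significant", "potent", "effective")

DEFAULT_N_RESULTS = 10


@dataclass
class SearchResult:
    title: str = ""
    link: str = ""
    content: str = ""


@dataclass
class SearchResultSet:
    results: list[SearchResult] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.results)


@dataclass(frozen=True)
class ResultScore:
    pair_hit: int
    positive_hit: int
    strong_hit: int

    @property
    def s(self) -> int:
        return self.pair_hit + self.positive_hit + self.strong_hit


@dataclass
class SearchEvidence:
    drug: str
    target: str
    per_result: list[ResultScore]
    total: int          # T
    maximum: int        # M = 3n
    score: float        # D = round(T/M, 2), 0 when M = 0
    summary: str


def build_query(drug: str, target: str) -> str:
    """Search query: the two names plus the literal term \"interaction\"."""
    drug, target = drug.strip(), target.strip()
    if not drug or not target:
        raise ContractError("drug and target names must be non-empty")
    return f"{drug} {target} interaction"


def _searchable_text(r: SearchResult) -> str:
    # Links carry no prose; indicators scan title + content only.
    return f"{r.title} {r.content}".casefold()


def score_result(r: SearchResult, drug: str, target: str,
                 positive_keywords=DEFAULT_POSITIVE_KEYWORDS,
                 strong_keywords=DEFAULT_STRONG_KEYWORDS) -> ResultScore:
    """Evaluate the three indicators for one result.

    Matching is case-insensitive plain substring, so "binds" also matches
    "bindings"; keyword lists are configurable where that is too loose.
    The pair indicator requires BOTH names.
    """
    if not positive_keywords or not strong_keywords:
        raise ContractError("keyword lists must be non-empty")
    text = _searchable_text(r)
    pair = int(drug.strip().casefold() in text and target.strip().casefold() in text)
    positive = int(any(k.casefold() in text for k in positive_keywords))
    strong = int(any(k.casefold() in text for k in strong_keywords))
    return ResultScore(pair_hit=pair, positive_hit=positive, strong_hit=strong)


def _round_half_even(numerator: int, denominator: int, places: int = 2) -> float:
    q = Decimal(numerator) / Decimal(denominator)
    return float(q.quantize(Decimal(10) ** -places, rounding=ROUND_HALF_EVEN))


def score_search(results: SearchResultSet, drug: str, target: str,
                 positive_keywords=DEFAULT_POSITIVE_KEYWORDS,
                 strong_keywords=DEFAULT_STRONG_KEYWORDS,
                 text_backend: TextBackend | None = None) -> SearchEvidence:
    """Score a result set: per-result indicators, totals, normalized D."""
    per = [score_result(r, drug, target, positive_keywords, strong_keywords)
           for r in results.results]
    total = sum(rs.s for rs in per)
    maximum = 3 * results.n
    score = _round_half_even(total, maximum) if maximum > 0 else 0.0
    summary = summarize_results(
        results, drug, target,
        backend=text_backend or TemplateTextBackend(),
        positive_keywords=positive_keywords, strong_keywords=strong_keywords)
    logger.info("Search channel %s-%s: T=%d M=%d D=%g", drug, target,
                total, maximum, score)
    return SearchEvidence(drug=drug, target=target, per_result=per,
                          total=total, maximum=maximum, score=score,
                          summary=summary)


def summarize_results(results: SearchResultSet, drug: str, target: str,
                      backend: TextBackend | None = None,
                      positive_keywords=DEFAULT_POSITIVE_KEYWORDS,
                      strong_keywords=DEFAULT_STRONG_KEYWORDS) -> str:
    """Digest of the result set via a text backend (template default).

    Backend failure degrades to the fixed fallback string and a logged
    warning; it never affects the numeric score.
    """
    backend = backend or TemplateTextBackend()
    combined = " ".join(_searchable_text(r) for r in results.results)
    found = [k for k in (*positive_keywords, *strong_keywords)
             if k.casefold() in combined]
    request = {
        "kind": "summary",
        "drug": drug,
        "target": target,
        "n_results": results.n,
        "keywords_found": found,
        "top_titles": [r.title for r in results.results[:3]],
    }
    try:
        return generate_text(request, backend)
    except BackendError as exc:
        logger.warning("summary backend failed (%s); using fallback", exc)
        return "summary unavailable"


# ---------------------------------------------------------------------------
# Retrieval backends


class SearchBackend:
    """Interface: map a query string to a list of results."""

    name = "abstract"

    def search(self, query: str, n: int) -> list[SearchResult]:  # pragma: no cover
        raise NotImplementedError


class FixtureSearchBackend(SearchBackend):
    """Offline backend reading a JSON mapping query -> result list.

    The fixture file maps each exact query string to a list of
    ``{"title": ..., "link": ..., "content": ...}`` objects.
    """

    name = "fixture"

    def __init__(self, fixture: str | dict):
        if isinstance(fixture, str):
            with open(fixture, encoding="utf-8") as fh:
                fixture = json.load(fh)
        self.fixture: dict[str, list[dict]] = fixture

    def search(self, query: str, n: int) -> list[SearchResult]:
        if query not in self.fixture:
            logger.warning("search fixture has no entry for query %r", query)
            return []
        return [SearchResult(title=d.get("title", ""), link=d.get("link", ""),
                             content=d.get("content", ""))
                for d in self.fixture[query][:n]]


class LiveSearchBackend(SearchBackend):
    """Web-search API backend; requires an API key and network access."""

    name = "live"

    def __init__(self, endpoint: str, api_key_env: str = "DTIFUSE_SEARCH_API_KEY"):
        import os
        self.endpoint = endpoint
        self.api_key = os.environ.get(api_key_env)
        if not self.api_key:
            raise RetrievalError(
                f"live search backend selected but {api_key_env} is unset")

    def search(self, query: str, n: int) -> list[SearchResult]:
        import urllib.error
        import urllib.parse
        import urllib.request
        url = f"{self.endpoint}?{urllib.parse.urlencode({'q': query, 'count': n})}"
        req = urllib.request.Request(url, headers={"Ocp-Apim-Subscription-Key": self.api_key})
        try:
            with urllib.request.urlopen(req, timeout=30) as resp:
                payload = json.load(resp)
        except (urllib.error.URLError, OSError, ValueError) as exc:
            raise RetrievalError(f"live search failed: {exc}") from exc
        pages = payload.get("webPages", {}).get("value", [])
        return [SearchResult(title=p.get("name", ""), link=p.get("url", ""),
                             content=p.get("snippet", ""))
                for p in pages[:n]]


def fetch_results(query: str, backend: SearchBackend,
                  n: int = DEFAULT_N_RESULTS) -> SearchResultSet:
    """Retrieve at most ``n`` results for ``query`` from ``backend``."""
    if n < 0:
        raise ContractError(f"n must be >= 0, got {n}")
    return SearchResultSet(results=backend.search(query, n)[:n])
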