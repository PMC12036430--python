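"""Knowledge-graph channel: path-based drug-target interaction scoring.

The score of a (drug, target) pair over an undirected drug-gene graph G is

    score(d, t) = 0                                    if d or t is not in G
                = 1.0                                  if edge d-t exists
                = max over simple paths p in P(d, t) of  w(p) / ln(1 + |p|)

clamped to [0, 1], where P(d, t) is the set of simple paths of at most
``max_hops`` edges (default 4), |p| is the hop count of p, and the path
weight

    w(p) = (1/|p|) * sum over consecutive pairs (n_i, n_{i+1}) of
           (deg(n_i) + deg(n_{i+1})) / (2 |V|)

rewards routes through well-connected nodes.  Division by ln(1 + |p|) makes
the score decrease with path length; a direct edge is pinned to exactly 1.0.
"""

from __future__ import annotations

import csv
import io
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import networkx as nx

from .errors import ConfigError, ContractError, GraphError, ParseError

logger = logging.getLogger(__name__)

NODE_KINDS = frozenset({"drug", "gene"})

#: Hard ceiling on enumerated paths per query; beyond it the score is a
#: lower bound and the evidence record is flagged as truncated.
DEFAULT_PATH_CAP = 10_000


def normalize_id(identifier: str) -> str:
    """Canonical node key: whitespace-trimmed, case-insensitive.

    No synonym resolution is attempted; mapping trade names or gene aliases
    onto graph identifiers is the caller's concern.
    """
    return identifier.strip().casefold()


@dataclass
class KnowledgeGraph:
    """Undirected labeled graph of drug and gene nodes.

    Nodes are keyed by their normalized identifier and carry ``label`` (the
    first-seen original spelling) and ``kind`` attributes; edges carry a
    ``sources`` set of provenance tags.  Duplicate edges collapse; their
    source tags merge.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, identifier: str) -> bool:
        return normalize_id(identifier) in self.graph

    def degree(self, identifier: str) -> int:
        key = normalize_id(identifier)
        if key not in self.graph:
            raise GraphError(f"node not in graph: {identifier!r}")
        return self.graph.degree[key]

    def label(self, key: str) -> str:
        return self.graph.nodes[key].get("label", key)

    def add_node(self, identifier: str, kind: str) -> str:
        key = normalize_id(identifier)
        if not key:
            raise GraphError("empty node identifier")
        if kind not in NODE_KINDS:
            raise GraphError(f"unknown node kind {kind!r} for {identifier!r}")
        if key in self.graph:
            existing = self.graph.nodes[key]["kind"]
            if existing != kind:
                raise GraphError(
                    f"node {identifier!r} declared both {existing!r} and {kind!r}"
                )
        else:
            self.graph.add_node(key, label=identifier.strip(), kind=kind)
        return key

    def add_edge(self, a: str, kind_a: str, b: str, kind_b: str,
                 source: str | None = None) -> None:
        ka = self.add_node(a, kind_a)
        kb = self.add_node(b, kind_b)
        if ka == kb:
            raise GraphError(f"self-loop on {a!r}")
        if self.graph.has_edge(ka, kb):
            if source:
                self.graph.edges[ka, kb]["sources"].add(source)
        else:
            self.graph.add_edge(ka, kb, sources={source} if source else set())


@dataclass(frozen=True)
class Path:
    """A simple path, stored as the ordered tuple of normalized node keys."""

    nodes: tuple[str, ...]

    @property
    def hop_count(self) -> int:
        return len(self.nodes) - 1


@dataclass(frozen=True)
class PathScore:
    path: Path
    weight: float
    combined_score: float


@dataclass
class KgEvidence:
    """Graph-channel evidence for one pair: score, best path, explanation."""

    drug: str
    target: str
    score: float
    best_path: PathScore | None
    all_paths: list[PathScore]
    reason: str
    truncated: bool = False


# ---------------------------------------------------------------------------
# Loading


def load_graph(source: str | TextIO | Iterable[str],
               on_self_loop: str = "warn") -> KnowledgeGraph:
    """Load an edge list into a :class:`KnowledgeGraph`.

    ``source`` is a file path, an open text stream, or an iterable of lines.
    Rows are ``node_a,kind_a,node_b,kind_b[,source]``, comma- or
    tab-separated; a header row matching those column names is skipped.
    ``on_self_loop`` is ``"warn"`` (drop the row) or ``"error"``.
    """
    if on_self_loop not in ("warn", "error"):
        raise ConfigError(f"on_self_loop must be 'warn' or 'error', got {on_self_loop!r}")

    if isinstance(source, str):
        with open(source, encoding="utf-8", newline="") as fh:
            return load_graph(fh, on_self_loop=on_self_loop)
    if not hasattr(source, "read"):
        source = io.StringIO("\n".join(source))

    kg = KnowledgeGraph()
    for lineno, row in enumerate(csv.reader(_retab(source)), start=1):
        if not row or all(not c.strip() for c in row):
            continue
        if lineno == 1 and [c.strip().lower() for c in row[:4]] == [
                "node_a", "kind_a", "node_b", "kind_b"]:
            continue
        if len(row) not in (4, 5):
            raise ParseError(f"expected 4 or 5 columns, got {len(row)}", line=lineno)
        a, kind_a, b, kind_b = (c.strip() for c in row[:4])
        src = row[4].strip() if len(row) == 5 and row[4].strip() else None
        if not a or not b:
            raise ParseError("empty node identifier", line=lineno)
        if kind_a.lower() not in NODE_KINDS or kind_b.lower() not in NODE_KINDS:
            raise ParseError(
                f"node kinds must be drug/gene, got {kind_a!r}/{kind_b!r}", line=lineno)
        if normalize_id(a) == normalize_id(b):
            if on_self_loop == "error":
                raise ParseError(f"self-loop on {a!r}", line=lineno)
            logger.warning("dropping self-loop row at line %d (%r)", lineno, a)
            continue
        try:
            kg.add_edge(a, kind_a.lower(), b, kind_b.lower(), src)
        except GraphError as exc:
            raise ParseError(str(exc), line=lineno) from exc
    logger.info("loaded knowledge graph: %d nodes, %d edges", kg.n_nodes, kg.n_edges)
    return kg


def _retab(stream: TextIO) -> Iterable[str]:
    # Accept TSV or CSV row by row: tabs win if present on the line.
    for line in stream:
        yield line.replace("\t", ",") if "\t" in line else line


# ---------------------------------------------------------------------------
# Scoring


def enumerate_paths(kg: KnowledgeGraph, drug: str, target: str,
                    max_hops: int = 4,
                    path_cap: int | None = DEFAULT_PATH_CAP) -> tuple[list[Path], bool]:
    """All simple paths from ``drug`` to ``target`` with 1..max_hops edges.

    Returns ``(paths, truncated)``; paths are sorted by (hop count, node
    sequence) so the order is deterministic and seed-free.  Absent endpoints
    give an empty list.  ``truncated`` is True when ``path_cap`` stopped the
    enumeration early, in which case the list is a subset.
    """
    if max_hops < 1:
        raise ConfigError(f"max_hops must be >= 1, got {max_hops}")
    d, t = normalize_id(drug), normalize_id(target)
    if d not in kg.graph or t not in kg.graph or d == t:
        return [], False
    paths: list[Path] = []
    truncated = False
    for node_list in nx.all_simple_paths(kg.graph, d, t, cutoff=max_hops):
        paths.append(Path(tuple(node_list)))
        if path_cap is not None and len(paths) >= path_cap:
            truncated = True
            logger.warning(
                "path cap %d reached for %s-%s; score is a lower bound",
                path_cap, drug, target)
            break
    paths.sort(key=lambda p: (p.hop_count, p.nodes))
    return paths, truncated


def path_weight(kg: KnowledgeGraph, path: Path) -> float:
    """Degree weight w(p): mean over edges of (deg(u)+deg(v)) / (2|V|)."""
    nodes = path.nodes
    if len(nodes) < 2:
        raise ContractError("path must have at least one hop")
    if len(set(nodes)) != len(nodes):
        raise ContractError("path repeats a node")
    if kg.n_nodes < 2:
        raise ContractError("graph must have at least 2 nodes")
    g = kg.graph
    total = 0.0
    for u, v in zip(nodes, nodes[1:]):
        if not g.has_edge(u, v):
            raise ContractError(f"edge {u!r}-{v!r} not in graph")
        total += (g.degree[u] + g.degree[v]) / (2 * kg.n_nodes)
    return total / path.hop_count


def combined_score(weight: float, hop_count: int) -> float:
    """Length-discounted path score w(p)/ln(1+|p|), clamped to [0, 1]."""
    return min(1.0, weight / math.log(1 + hop_count))


def score_path(kg: KnowledgeGraph, path: Path) -> PathScore:
    w = path_weight(kg, path)
    return PathScore(path=path, weight=w,
                     combined_score=combined_score(w, path.hop_count))


def dti_kg_score(kg: KnowledgeGraph, drug: str, target: str,
                 max_hops: int = 4,
                 path_cap: int | None = DEFAULT_PATH_CAP) -> KgEvidence:
    """Path-based interaction score with a best-path explanation.

    Score is 0 when either endpoint is missing or no path of at most
    ``max_hops`` hops exists, exactly 1.0 for a direct edge, and otherwise
    the maximum length-discounted path weight.  Ties among equally scored
    paths break toward the shorter, lexicographically smaller path.
    """
    if max_hops < 1:
        raise ConfigError(f"max_hops must be >= 1, got {max_hops}")
    d, t = normalize_id(drug), normalize_id(target)
    if d not in kg.graph or t not in kg.graph:
        return KgEvidence(
            drug=drug, target=target, score=0.0, best_path=None, all_paths=[],
            reason=f"No knowledge-graph entry for {drug} and/or {target}.")

    paths, truncated = enumerate_paths(kg, drug, target, max_hops, path_cap)
    if not paths:
        return KgEvidence(
            drug=drug, target=target, score=0.0, best_path=None, all_paths=[],
            reason=(f"Found 0 paths between {drug} and {target} "
                    f"within {max_hops} hops."))

    scored = [score_path(kg, p) for p in paths]
    # Descending combined score; ties -> fewer hops, then node sequence.
    scored.sort(key=lambda ps: (-ps.combined_score, ps.path.hop_count, ps.path.nodes))
    direct = kg.graph.has_edge(d, t)
    if direct:
        # A truncated enumeration may have dropped the 1-hop path; rebuild it.
        best = next((ps for ps in scored if ps.path.hop_count == 1),
                    None) or score_path(kg, Path((d, t)))
        score = 1.0
    else:
        best = scored[0]
        score = best.combined_score
    return KgEvidence(
        drug=drug, target=target, score=score, best_path=best,
        all_paths=scored, truncated=truncated,
        reason=_render_reason(kg, drug, target, score, scored, direct, truncated))


def _render_reason(kg: KnowledgeGraph, drug: str, target: str, score: float,
                   scored: list[PathScore], direct: bool, truncated: bool,
                   top: int = 3) -> str:
    lines = [f"Found {len(scored)}{'+' if truncated else ''} paths between "
             f"{drug} and {target}. Best score: {score:.3f}"]
    if direct:
        lines[0] += " (direct interaction)"
    for k, ps in enumerate(scored[:top], start=1):
        route = " → ".join(kg.label(n) for n in ps.path.nodes)
        lines.append(f"Path {k}: {route} (score: {ps.combined_score:.3f})")
    return "\n".join(lines)
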