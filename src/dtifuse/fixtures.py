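"""Seeded synthetic fixtures: graphs with planted paths, search-result sets
with planted indicator counts, predictor lookup tables, and labels.

Every generator is a pure function of its spec (seed included), so
identical specs reproduce identical artifacts byte for byte.  Planted
ground truth is constructed to be exactly recoverable: a ``direct`` pair
gets the edge d-t; a ``k_hop:k`` pair gets a node-disjoint chain of exactly
k edges and no shorter route (background edges never touch planted nodes);
a ``none`` pair stays disconnected.  Search profiles plant indicator counts
(pair, positive, strong) among the n results so T and D are known in
advance.

These are stylized stand-ins for curated interaction databases and live
web search: node naming, text, and degree structure are deliberately
synthetic.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .backends import MockPredictor, PredictorInput
from .errors import SpecError
from .evaluation import LabeledPair
from .kg import KnowledgeGraph
from .search import SearchResult, build_query

Profile = tuple[int, int, int]  # (pair_hits, positive_hits, strong_hits)

#: Keyword pools the search-text planter draws from (first of each list).
_POSITIVE_WORDS = ("binds", "interacts", "activates", "modulates")
_STRONG_WORDS = ("significant", "strong", "potent", "effective")


@dataclass
class FixtureSpec:
    seed: int = 0
    n_drugs: int = 8
    n_genes: int = 10
    edge_density: float = 0.15
    #: (drug, target, relation) with relation in {"direct", "k_hop:<k>", "none"}
    planted_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    #: per-pair (pair_hits, positive_hits, strong_hits) among ``search_n``
    #: results; a single tuple applies to every planted pair
    search_profile: dict[tuple[str, str], Profile] | Profile | None = None
    search_n: int = 10
    #: relation class -> binary label
    label_rule: dict[str, int] = field(
        default_factory=lambda: {"direct": 1, "k_hop": 1, "none": 0})

    def __post_init__(self):
        if not (0 < self.edge_density <= 1):
            raise SpecError(f"edge_density must be in (0, 1], got {self.edge_density}")
        if self.n_drugs < 1 or self.n_genes < 1:
            raise SpecError("n_drugs and n_genes must be positive")
        for d, t, rel in self.planted_pairs:
            _parse_relation(rel)
            if not d.strip() or not t.strip():
                raise SpecError("planted pair names must be non-empty")

    def profile_for(self, drug: str, target: str) -> Profile:
        if self.search_profile is None:
            return (0, 0, 0)
        if isinstance(self.search_profile, dict):
            return self.search_profile.get((drug, target), (0, 0, 0))
        return self.search_profile


def _parse_relation(rel: str) -> int | None:
    """Return hop count for the planted relation: 1, k, or None for 'none'."""
    if rel == "direct":
        return 1
    if rel == "none":
        return None
    if rel.startswith("k_hop:"):
        k = int(rel.split(":", 1)[1])
        if k < 1:
            raise SpecError(f"planted hop count must be >= 1, got {k}")
        return k
    raise SpecError(f"unknown planted relation {rel!r}")


@dataclass
class PlantedNote:
    drug: str
    target: str
    relation: str
    hops: int | None  # None => no path exists


def make_graph(spec: FixtureSpec) -> tuple[KnowledgeGraph, list[PlantedNote]]:
    """Random drug-gene graph with every planted relation built in exactly."""
    kg = KnowledgeGraph()
    drugs = [f"D{i:03d}" for i in range(1, spec.n_drugs + 1)]
    genes = [f"G{i:03d}" for i in range(1, spec.n_genes + 1)]
    reserved: set[str] = set()
    notes: list[PlantedNote] = []

    # Pools of spare intermediate nodes for planted chains.
    spare = [(g, "gene") for g in genes] + [(d, "drug") for d in drugs]
    planted_names = {n.strip().casefold()
                     for d, t, _ in spec.planted_pairs for n in (d, t)}
    spare = [(n, k) for n, k in spare if n.casefold() not in planted_names]

    for d, t, rel in spec.planted_pairs:
        hops = _parse_relation(rel)
        kg.add_node(d, "drug")
        kg.add_node(t, "gene")
        reserved.update({d.casefold(), t.casefold()})
        if hops is None:
            notes.append(PlantedNote(d, t, rel, None))
            continue
        if hops == 1:
            kg.add_edge(d, "drug", t, "gene", source="planted")
            notes.append(PlantedNote(d, t, rel, 1))
            continue
        if hops - 1 > len(spare):
            raise SpecError(
                f"planted chain {rel} for ({d}, {t}) needs {hops - 1} "
                f"intermediate nodes; only {len(spare)} available")
        chain = [spare.pop(0) for _ in range(hops - 1)]
        prev, prev_kind = d, "drug"
        for name, kind in chain:
            kg.add_edge(prev, prev_kind, name, kind, source="planted")
            reserved.add(name.casefold())
            prev, prev_kind = name, kind
        kg.add_edge(prev, prev_kind, t, "gene", source="planted")
        notes.append(PlantedNote(d, t, rel, hops))

    # Background bipartite edges among unreserved pool nodes only, so no
    # shortcut can undercut a planted chain or reconnect a 'none' pair.
    rng = np.random.default_rng(spec.seed)
    free_drugs = [d for d in drugs if d.casefold() not in reserved]
    free_genes = [g for g in genes if g.casefold() not in reserved]
    for d in free_drugs:
        for g in free_genes:
            if rng.random() < spec.edge_density:
                kg.add_edge(d, "drug", g, "gene", source="background")
    return kg, notes


def make_search_fixture(spec: FixtureSpec) -> dict[str, list[dict]]:
    """Query -> result-list mapping realizing each pair's indicator profile.

    Result i of n carries both names iff i < pair_hits, one positive keyword
    iff i < positive_hits, and one strong keyword iff i < strong_hits; the
    remaining text is neutral filler free of names and keywords.
    """
    fixture: dict[str, list[dict]] = {}
    for d, t, _rel in spec.planted_pairs:
        pair_hits, pos_hits, strong_hits = spec.profile_for(d, t)
        n = spec.search_n
        if max(pair_hits, pos_hits, strong_hits) > n:
            raise SpecError(
                f"profile {(pair_hits, pos_hits, strong_hits)} exceeds n={n} "
                f"for pair ({d}, {t})")
        results = []
        for i in range(n):
            sentences = ["Archived laboratory record entry."]
            if i < pair_hits:
                sentences.append(f"Co-assay of {d} and {t} was documented.")
            if i < pos_hits:
                sentences.append(f"The compound {_POSITIVE_WORDS[0]} the enzyme.")
            if i < strong_hits:
                sentences.append(f"The observed effect was {_STRONG_WORDS[0]}.")
            results.append({
                "title": f"Result {i + 1}",
                "link": f"https://example.org/{d}/{t}/{i + 1}".lower().replace(" ", "-"),
                "content": " ".join(sentences),
            })
        fixture[build_query(d, t)] = results
    return fixture


def make_lookup(spec: FixtureSpec) -> dict[tuple[str, str], float]:
    """Deterministic predictor lookup table for the planted pairs."""
    mock = MockPredictor(seed=spec.seed)
    return {(d, t): mock.predict(PredictorInput(drug_name=d, target_name=t))
            for d, t, _ in spec.planted_pairs}


def make_labels(spec: FixtureSpec,
                notes: list[PlantedNote] | None = None) -> list[LabeledPair]:
    """Binary labels for the planted pairs via the spec's label rule."""
    out = []
    for d, t, rel in spec.planted_pairs:
        cls = "k_hop" if rel.startswith("k_hop") else rel
        out.append(LabeledPair(drug=d, target=t, label=spec.label_rule[cls]))
    return out


def write_fixture_dir(spec: FixtureSpec, out_dir: str) -> dict[str, str]:
    """Materialize all fixture artifacts as plain-text files.

    Writes ``edges.tsv``, ``search.json``, ``lookup.csv``, ``labels.csv``
    (and ``pairs.csv`` for batch runs); returns the path map.
    """
    os.makedirs(out_dir, exist_ok=True)
    kg, _notes = make_graph(spec)
    paths = {name: os.path.join(out_dir, fname) for name, fname in [
        ("edges", "edges.tsv"), ("search", "search.json"),
        ("lookup", "lookup.csv"), ("labels", "labels.csv"),
        ("pairs", "pairs.csv")]}

    with open(paths["edges"], "w", encoding="utf-8", newline="") as fh:
        fh.write("node_a\tkind_a\tnode_b\tkind_b\tsource\n")
        for u, v, data in sorted(kg.graph.edges(data=True)):
            src = ",".join(sorted(data["sources"])) if data["sources"] else ""
            fh.write(f"{kg.label(u)}\t{kg.graph.nodes[u]['kind']}\t"
                     f"{kg.label(v)}\t{kg.graph.nodes[v]['kind']}\t{src}\n")

    with open(paths["search"], "w", encoding="utf-8") as fh:
        json.dump(make_search_fixture(spec), fh, indent=1, sort_keys=True)

    with open(paths["lookup"], "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["drug", "target", "score"])
        for (d, t), s in make_lookup(spec).items():
            writer.writerow([d, t, repr(s)])

    with open(paths["labels"], "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["drug", "target", "label"])
        for lab in make_labels(spec):
            writer.writerow([lab.drug, lab.target, lab.label])

    with open(paths["pairs"], "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["drug", "target"])
        for d, t, _ in spec.planted_pairs:
            writer.writerow([d, t])
    return paths


# ---------------------------------------------------------------------------
# The pinned end-to-end example


@dataclass
class WorkedExample:
    """A fully pinned three-channel run for the pair Vandetanib-MARK2.

    The ML channel is served by a lookup table, the search channel by a
    fixture whose indicator profile (9 pair hits, 0, 0) over 10 results
    yields D = 0.3 exactly, and the graph channel by the test/simulate-only
    score-override hook (its pinned value cannot arise from a small
    constructed graph).  Fusing the three gives a final score of 0.34045.
    """

    drug: str = "Vandetanib"
    target: str = "MARK2"
    ai_score: float = 7.260064194269944e-06
    kg_score: float = 0.7213475204444817
    search_score: float = 0.3
    expected_final: float = 0.34045

    @property
    def lookup(self) -> dict[tuple[str, str], float]:
        return {(self.drug, self.target): self.ai_score}

    @property
    def kg_override(self) -> dict[tuple[str, str], float]:
        return {(self.drug, self.target): self.kg_score}

    def search_fixture(self) -> dict[str, list[dict]]:
        spec = FixtureSpec(
            planted_pairs=[(self.drug, self.target, "none")],
            search_profile=(9, 0, 0), search_n=10)
        return make_search_fixture(spec)


def make_worked_example() -> WorkedExample:
    return WorkedExample()
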