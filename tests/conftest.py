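"""Shared fixtures and independent oracles for the test suite.

The oracles re-derive every score from first principles (plain dict
adjacency, recursive enumeration, explicit arithmetic) without touching
the package's graph machinery, so they stay independent of the code paths
they check.
"""

from __future__ import annotations

import math
import os
from types import SimpleNamespace

import numpy as np
import pytest

from dtifuse import KnowledgeGraph, load_graph

DATA_DIR = os.path.join(os.path.dirname(__file__), "data")


# ---------------------------------------------------------------------------
# Brute-force oracles (independent of dtifuse.kg / dtifuse.evaluation)


def dfs_paths(adj: dict[str, set[str]], s: str, t: str, max_hops: int):
    """Exhaustive recursive simple-path enumeration; returns a set of tuples."""
    found = set()

    def walk(node, visited, path):
        if len(path) - 1 > max_hops:
            return
        if node == t and len(path) >= 2:
            found.add(tuple(path))
            return
        if len(path) - 1 == max_hops:
            return
        for nxt in adj.get(node, ()):
            if nxt not in visited:
                walk(nxt, visited | {nxt}, path + [nxt])

    if s in adj and t in adj and s != t:
        walk(s, {s}, [s])
    return found


def oracle_path_weight(adj: dict[str, set[str]], path: tuple[str, ...]) -> float:
    n_nodes = len(adj)
    hops = len(path) - 1
    total = sum((len(adj[u]) + len(adj[v])) / (2 * n_nodes)
                for u, v in zip(path, path[1:]))
    return total / hops


def oracle_kg_score(adj: dict[str, set[str]], d: str, t: str,
                    max_hops: int = 4) -> float:
    if d not in adj or t not in adj:
        return 0.0
    if t in adj[d]:
        return 1.0
    paths = dfs_paths(adj, d, t, max_hops)
    if not paths:
        return 0.0
    best = max(min(1.0, oracle_path_weight(adj, p) / math.log(len(p)))
               for p in paths)
    return best


def oracle_auroc(scores, labels) -> float:
    """Concordant-pair count over all pos x neg pairs, half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else 0.5 if p == n else 0.0
    return total / (len(pos) * len(neg))


def random_adjacency(rng: np.random.Generator, n_nodes: int,
                     edge_prob: float) -> dict[str, set[str]]:
    """Random undirected graph as a plain adjacency dict (all nodes present)."""
    names = [f"N{i}" for i in range(n_nodes)]
    adj = {n: set() for n in names}
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                adj[names[i]].add(names[j])
                adj[names[j]].add(names[i])
    return adj


def adjacency_to_graph(adj: dict[str, set[str]]) -> KnowledgeGraph:
    """Mirror an adjacency dict into a KnowledgeGraph (drug/gene alternating)."""
    kg = KnowledgeGraph()
    kind = {n: ("drug" if i % 2 == 0 else "gene")
            for i, n in enumerate(sorted(adj))}
    for n in sorted(adj):
        kg.add_node(n, kind[n])
    for u in sorted(adj):
        for v in sorted(adj[u]):
            if u < v:
                kg.add_edge(u, kind[u], v, kind[v])
    return kg


# ---------------------------------------------------------------------------
# Fixtures


@pytest.fixture(scope="session")
def kg_small_path() -> str:
    return os.path.join(DATA_DIR, "kg_small.tsv")


@pytest.fixture(scope="session")
def kg_small(kg_small_path):
    return load_graph(kg_small_path)


@pytest.fixture(scope="session")
def oracle():
    return SimpleNamespace(
        dfs_paths=dfs_paths,
        path_weight=oracle_path_weight,
        kg_score=oracle_kg_score,
        auroc=oracle_auroc,
        random_adjacency=random_adjacency,
        adjacency_to_graph=adjacency_to_graph,
    )


@pytest.fixture()
def worked_example():
    from dtifuse import make_worked_example
    return make_worked_example()


@pytest.fixture()
def worked_example_config(worked_example):
    from dtifuse import RunConfig
    ex = worked_example
    return RunConfig(mode="test", ai_backend="lookup", ai_lookup=ex.lookup,
                     search_fixture=ex.search_fixture(),
                     kg_score_override=ex.kg_override)
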