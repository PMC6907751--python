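"""Shared fixtures: small hand-checkable ontologies, random-DAG makers,
and brute-force oracles kept deliberately independent of the library's
implementations."""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from genesupport.ontology import OntologyGraph


@pytest.fixture
def diamond() -> OntologyGraph:
    """root -> a, root -> b, a -> c, b -> c: one multi-parent node."""
    return OntologyGraph.from_edges(
        [("root", "a"), ("root", "b"), ("a", "c"), ("b", "c")]
    )


@pytest.fixture
def seven_term_tree() -> OntologyGraph:
    """Balanced-ish tree of 7 terms: root with children x and y, x with
    children x1, x2; y with children y1, y2.  Leaves have IC ln 7."""
    return OntologyGraph.from_edges(
        [("root", "x"), ("root", "y"),
         ("x", "x1"), ("x", "x2"), ("y", "y1"), ("y", "y2")]
    )


def random_dag(rng: np.random.Generator, n_terms: int) -> OntologyGraph:
    """Random rooted DAG: each non-root node gets 1-2 parents among the
    earlier nodes, guaranteeing acyclicity and root-reachability."""
    terms = [f"n{i}" for i in range(n_terms)]
    edges = []
    for i in range(1, n_terms):
        n_parents = 1 + int(rng.random() < 0.4 and i > 1)
        parents = rng.choice(i, size=min(n_parents, i), replace=False)
        for p in parents:
            edges.append((terms[p], terms[i]))
    return OntologyGraph.from_edges(edges, root=terms[0])


# ---------------------------------------------------------------------------
# independent oracles


def oracle_descendants(graph: nx.DiGraph, term: str) -> set[str]:
    """Descendant set by explicit depth-first traversal."""
    seen: set[str] = set()
    stack = list(graph.successors(term))
    while stack:
        node = stack.pop()
        if node not in seen:
            seen.add(node)
            stack.extend(graph.successors(node))
    return seen


def oracle_ic(ontology: OntologyGraph) -> dict[str, float]:
    n = ontology.graph.number_of_nodes()
    return {
        t: -math.log((len(oracle_descendants(ontology.graph, t)) + 1) / n)
        for t in ontology.graph.nodes
    }


def oracle_ancestors(graph: nx.DiGraph, term: str) -> set[str]:
    rev = graph.reverse()
    return oracle_descendants(rev, term) | {term}


def oracle_mica(ontology: OntologyGraph, ic: dict[str, float],
                t1: str, t2: str) -> str:
    """Exhaustive search over the ancestor intersection."""
    common = oracle_ancestors(ontology.graph, t1) & oracle_ancestors(
        ontology.graph, t2
    )
    best = sorted(common, key=lambda t: (-ic[t], t))
    return best[0]


def oracle_risk_ratio(phases, evidence, to_phase: int, from_phase: int) -> float:
    """Two-by-two at-or-beyond counting with explicit loops."""
    a = b = c = d = 0
    for h, e in zip(phases, evidence):
        if e:
            a += h >= to_phase
            b += h >= from_phase
        else:
            c += h >= to_phase
            d += h >= from_phase
    return (a / b) / (c / d)


@pytest.fixture
def link_frame():
    """Factory for minimal association-set frames."""

    def make(rows):
        return pd.DataFrame(
            rows,
            columns=["gene_id", "trait_heading", "source", "channels",
                     "date_added", "last_date", "deleterious_r2"],
        )

    return make
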