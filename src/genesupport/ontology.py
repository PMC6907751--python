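"""Trait-heading ontology: information content and semantic similarity.

Disease indications and genetically associated traits are linked through a
rooted directed acyclic graph of controlled headings (a MeSH-style
hierarchy).  The specificity of a heading is measured by its information
content, computed from the number of descendants: a heading covering the
whole vocabulary (the root) carries no information, a leaf is maximally
specific.  Pairwise similarity between headings combines Lin similarity
with per-trait-normalized Resnik similarity, both driven by the most
informative common ancestor (MICA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd


class OntologyError(ValueError):
    """Structural problem with an ontology graph (cycle, unreachable term)."""


class UnknownTermError(KeyError):
    """A heading was requested that is not in the ontology."""


@dataclass(frozen=True)
class OntologyGraph:
    """Rooted DAG of trait/indication headings.

    Edges point parent -> child.  Every term must be reachable from the
    root, there are no self-edges, and the graph is acyclic.
    """

    graph: nx.DiGraph
    root: str

    def __post_init__(self) -> None:
        g = self.graph
        if self.root not in g:
            raise OntologyError(f"root {self.root!r} not among terms")
        if any(u == v for u, v in g.edges):
            bad = next((u, v) for u, v in g.edges if u == v)
            raise OntologyError(f"self-edge {bad[0]!r}->{bad[1]!r}")
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            u, v = cycle[0][0], cycle[0][1]
            raise OntologyError(f"cycle detected through edge {u!r}->{v!r}")
        reachable = nx.descendants(g, self.root) | {self.root}
        missing = set(g.nodes) - reachable
        if missing:
            raise OntologyError(
                f"{len(missing)} terms unreachable from root, e.g. "
                f"{sorted(missing)[0]!r}"
            )

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def require(self, term: str) -> None:
        if term not in self.graph:
            raise UnknownTermError(term)

    def ancestors_inclusive(self, term: str) -> set[str]:
        """Ancestors of ``term`` including the term itself."""
        self.require(term)
        return nx.ancestors(self.graph, term) | {term}

    @classmethod
    def from_edges(cls, edges, root: str | None = None) -> "OntologyGraph":
        """Build from (parent, child) pairs; the root is inferred as the
        unique term with no parent unless given explicitly."""
        g = nx.DiGraph()
        g.add_edges_from(edges)
        if root is None:
            roots = [n for n in g.nodes if g.in_degree(n) == 0]
            if len(roots) != 1:
                raise OntologyError(
                    f"expected exactly one parentless term, found {sorted(roots)}"
                )
            root = roots[0]
        elif root not in g:
            g.add_node(root)
        return cls(graph=g, root=root)

    @classmethod
    def from_tree_numbers(cls, table: pd.DataFrame, root: str = "ROOT") -> "OntologyGraph":
        """Build from a MeSH-style tree-number table.

        ``table`` has columns ``term`` and ``tree_number``; a term is the
        parent of another when one of its tree numbers is the longest
        proper dot-separated prefix of the child's tree number.  Top-level
        tree numbers hang off a synthetic root.
        """
        by_number = dict(zip(table["tree_number"], table["term"]))
        edges = []
        for number, term in by_number.items():
            parts = number.split(".")
            parent = None
            for k in range(len(parts) - 1, 0, -1):
                prefix = ".".join(parts[:k])
                if prefix in by_number:
                    parent = by_number[prefix]
                    break
            edges.append((parent if parent is not None else root, term))
        return cls.from_edges(edges, root=root)


def compute_information_content(ontology: OntologyGraph) -> dict[str, float]:
    """Information content per heading from descendant counts.

    IC(c) = -ln((|descendants(c)| + 1) / N) with N the vocabulary size and
    descendants counted over the full DAG (a node reachable through
    multiple paths counts once).  The root has IC 0; leaves are maximal.
    """
    import math

    n = ontology.graph.number_of_nodes()
    ic = {}
    for term in ontology.graph.nodes:
        n_desc = len(nx.descendants(ontology.graph, term))
        ic[term] = -math.log((n_desc + 1) / n)
    return ic


def most_informative_common_ancestor(
    ontology: OntologyGraph, ic: dict[str, float], t1: str, t2: str
) -> str:
    """Common ancestor (self-inclusive) with maximal IC; ties broken by
    lexicographic term identifier for determinism."""
    common = ontology.ancestors_inclusive(t1) & ontology.ancestors_inclusive(t2)
    return min(common, key=lambda t: (-ic[t], t))


def resnik_similarity(
    ontology: OntologyGraph, ic: dict[str, float], t1: str, t2: str
) -> float:
    """IC of the most informative common ancestor."""
    return ic[most_informative_common_ancestor(ontology, ic, t1, t2)]


def lin_similarity(
    ontology: OntologyGraph, ic: dict[str, float], t1: str, t2: str
) -> float:
    """2*IC(MICA) / (IC(t1) + IC(t2)); 0 when both ICs vanish."""
    denom = ic[t1] + ic[t2]
    if denom == 0.0:
        ontology.require(t1)
        ontology.require(t2)
        return 0.0
    return 2.0 * resnik_similarity(ontology, ic, t1, t2) / denom


def combined_similarity(
    ontology: OntologyGraph, ic: dict[str, float], t1: str, t2: str
) -> float:
    """Mean of Lin similarity and per-trait-normalized Resnik similarity.

    Resnik similarity is standardized so each trait's self-similarity is
    its maximum (division by the trait's own IC), computed for both
    argument orders and averaged; the result is clipped to [0, 1].
    Pairs involving the root (IC 0) cannot be normalized and score 0.
    """
    r = resnik_similarity(ontology, ic, t1, t2)
    ic1, ic2 = ic[t1], ic[t2]
    if ic1 == 0.0 or ic2 == 0.0:
        return 0.0
    lin = 2.0 * r / (ic1 + ic2)
    norm_resnik = 0.5 * (r / ic1 + r / ic2)
    return min(1.0, max(0.0, 0.5 * (lin + norm_resnik)))


@dataclass
class TraitSimilarityFunction:
    """The trait similarity S_T: pairs of headings -> [0, 1].

    Computed values come from :func:`combined_similarity`; manual override
    entries (curated similarities for trait pairs the hierarchy keeps
    apart, e.g. a disease and its quantitative endophenotype) replace the
    computed value and are flagged so analyses can be rerun without them.
    """

    ontology: OntologyGraph
    ic: dict[str, float]
    overrides: dict[tuple[str, str], float] = field(default_factory=dict)
    _cache: dict[tuple[str, str], float] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for (a, b), v in self.overrides.items():
            self.ontology.require(a)
            self.ontology.require(b)
            if not (0.0 <= v <= 1.0):
                raise ValueError(
                    f"manual similarity for ({a!r}, {b!r}) is {v}, outside [0, 1]"
                )

    def _key(self, t1: str, t2: str) -> tuple[str, str]:
        return (t1, t2) if t1 <= t2 else (t2, t1)

    def computed(self, t1: str, t2: str) -> float:
        key = self._key(t1, t2)
        if key not in self._cache:
            self._cache[key] = combined_similarity(self.ontology, self.ic, *key)
        return self._cache[key]

    def __call__(self, t1: str, t2: str, include_manual: bool = True) -> float:
        if include_manual:
            key = self._key(t1, t2)
            if key in self.overrides:
                return self.overrides[key]
        return self.computed(t1, t2)

    def provenance(self, t1: str, t2: str) -> str:
        return "manual" if self._key(t1, t2) in self.overrides else "computed"


def build_similarity_function(
    ontology: OntologyGraph,
    manual_overrides: pd.DataFrame | None = None,
) -> TraitSimilarityFunction:
    """Assemble S_T from an ontology and an optional override table with
    columns ``term_a``, ``term_b``, ``similarity``."""
    ic = compute_information_content(ontology)
    overrides: dict[tuple[str, str], float] = {}
    if manual_overrides is not None:
        for row in manual_overrides.itertuples(index=False):
            a, b = str(row.term_a), str(row.term_b)
            key = (a, b) if a <= b else (b, a)
            overrides[key] = float(row.similarity)
    return TraitSimilarityFunction(ontology=ontology, ic=ic, overrides=overrides)


def pairwise_similarity_table(
    s_t: TraitSimilarityFunction,
    terms: list[str] | None = None,
    include_manual: bool = True,
) -> pd.DataFrame:
    """All unordered pairs (including self-pairs) as a long table with
    columns term_a, term_b, similarity, provenance."""
    if terms is None:
        terms = sorted(s_t.ontology.terms)
    rows = []
    for i, a in enumerate(terms):
        for b in terms[i:]:
            rows.append(
                (a, b, s_t(a, b, include_manual=include_manual), s_t.provenance(a, b))
            )
    return pd.DataFrame(rows, columns=["term_a", "term_b", "similarity", "provenance"])
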