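"""Genetic-evidence functions for target-indication pairs.

Given an association set A of gene-trait links and a trait similarity
function S_T, the pairwise score between two (gene, trait) queries is
S = S_T(t1, t2) when the genes coincide, else 0.  Continuous evidence
E_C(g, t) is the maximum score against the elements of A, i.e. the
similarity between the indication and the most similar trait genetically
associated with the gene.  Binary evidence E_D thresholds E_C at a
cutoff (default 0.7; 0.73 is the recalibrated preset compensating for
vocabulary-version drift in computed similarities).

A gene with no association at all in A yields the sentinel
:data:`NO_ASSOCIATION`, deliberately distinct from an E_C of 0: the
approval model treats "no association exists" as its own reference
branch, while "an association to a completely dissimilar trait" enters
the evidence polynomial at similarity 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .ontology import TraitSimilarityFunction


class _NoAssociation:
    """Sentinel: the query gene has no entry in the association set."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "NO_ASSOCIATION"

    def __bool__(self) -> bool:
        return False


NO_ASSOCIATION = _NoAssociation()

CUTOFF_PRESETS = {"original": 0.7, "recalibrated": 0.73}


@dataclass(frozen=True)
class EvidenceScore:
    """Evidence for one (gene, indication) query against one source."""

    e_c: float | _NoAssociation
    e_d: int
    n_similar: int


def pair_score(
    q1: tuple[str, str], q2: tuple[str, str], s_t: TraitSimilarityFunction
) -> float:
    """S((g1,t1),(g2,t2)) = S_T(t1,t2) if g1 == g2 else 0."""
    (g1, t1), (g2, t2) = q1, q2
    if g1 != g2:
        s_t.ontology.require(t1)
        s_t.ontology.require(t2)
        return 0.0
    return s_t(t1, t2)


def _gene_traits(links: pd.DataFrame, gene: str) -> list[str]:
    return links.loc[links["gene_id"] == gene, "trait_heading"].tolist()


def continuous_evidence(
    gene: str,
    indication: str,
    links: pd.DataFrame,
    s_t: TraitSimilarityFunction,
    include_manual: bool = True,
) -> float | _NoAssociation:
    """E_C(g, t): max similarity between the indication and any trait
    genetically linked to the gene; NO_ASSOCIATION if the gene is absent
    from the association set."""
    s_t.ontology.require(indication)
    traits = _gene_traits(links, gene)
    if not traits:
        return NO_ASSOCIATION
    return max(s_t(indication, t, include_manual=include_manual) for t in traits)


def binary_evidence(
    gene: str,
    indication: str,
    links: pd.DataFrame,
    s_t: TraitSimilarityFunction,
    cutoff: float = 0.7,
    include_manual: bool = True,
) -> int:
    """E_D(g, t) = 1 iff E_C(g, t) >= cutoff (boundary included);
    a gene without associations scores 0."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    e_c = continuous_evidence(gene, indication, links, s_t, include_manual)
    if e_c is NO_ASSOCIATION:
        return 0
    return int(e_c >= cutoff)


def eligible_by_association_count(
    indication: str,
    links: pd.DataFrame,
    s_t: TraitSimilarityFunction,
    cutoff: float = 0.7,
    min_count: int = 5,
    gene: str | None = None,
    include_manual: bool = True,
) -> int:
    """Eligibility gate for two-by-two analyses: at least ``min_count``
    associations to traits similar to the indication must exist.

    By default the count runs over all genes (per-indication reading);
    pass ``gene`` to restrict to that gene's associations instead.
    """
    if min_count < 0:
        raise ValueError("min_count must be nonnegative")
    s_t.ontology.require(indication)
    subset = links if gene is None else links.loc[links["gene_id"] == gene]
    n = sum(
        1
        for t in subset["trait_heading"]
        if s_t(indication, t, include_manual=include_manual) >= cutoff
    )
    return int(n >= min_count)


def score_pairs(
    pairs: pd.DataFrame,
    links: pd.DataFrame,
    s_t: TraitSimilarityFunction,
    cutoff: float = 0.7,
    min_count: int = 5,
    include_manual: bool = True,
) -> pd.DataFrame:
    """Score every (gene_id, indication) row of ``pairs`` against each
    association source present in ``links``.

    Returns a long table with columns gene_id, indication, source, e_c
    (NaN when the gene has no association for that source), has_assoc,
    e_d, n_similar, eligible.
    """
    out = []
    for source, src_links in links.groupby("source"):
        gene_traits: dict[str, list[str]] = {
            g: grp["trait_heading"].tolist()
            for g, grp in src_links.groupby("gene_id")
        }
        all_traits = src_links["trait_heading"].tolist()
        sim_count_cache: dict[str, int] = {}
        for row in pairs.itertuples(index=False):
            g, ind = row.gene_id, row.indication
            traits = gene_traits.get(g)
            if traits:
                sims = [s_t(ind, t, include_manual=include_manual) for t in traits]
                e_c: float | None = max(sims)
                n_similar = sum(s >= cutoff for s in sims)
                e_d = int(e_c >= cutoff)
                has_assoc = 1
            else:
                e_c, n_similar, e_d, has_assoc = None, 0, 0, 0
            if ind not in sim_count_cache:
                sim_count_cache[ind] = sum(
                    s_t(ind, t, include_manual=include_manual) >= cutoff
                    for t in all_traits
                )
            eligible = int(sim_count_cache[ind] >= min_count)
            out.append((g, ind, source, e_c, has_assoc, e_d, n_similar, eligible))
    return pd.DataFrame(
        out,
        columns=[
            "gene_id", "indication", "source", "e_c",
            "has_assoc", "e_d", "n_similar", "eligible",
        ],
    )
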