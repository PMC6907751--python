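"""Gene-trait association sets from GWAS-style and curated (OMIM-style) data.

GWAS rows associate a SNP with a trait heading; they become gene-trait
links through LD expansion of the lead SNP followed by three SNP-to-gene
channels: genomic distance, eQTL, and DHS-correlation.  Curated rows link
a gene to a trait directly.  All tables are plain pandas DataFrames with
the column contracts documented on each function.

Filter conventions (each chosen to match the stated rule):

* genome-wide significance: keep ``p_value <= 1e-8`` (boundary kept);
* LD expansion: keep partners with ``r2 >= threshold`` (inclusive);
* distance: closed window, gene body [start - w, end + w], 1-based;
* eQTL: strict ``p < cutoff``;
* DHS: keep ``perm_p <= cutoff`` (boundary kept), default cutoff 0.001,
  the resolution of a 1000-replicate permutation test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DELETERIOUS_SEVERITIES = frozenset({"HIGH", "MODERATE"})

GWAS_COLUMNS = [
    "snp_id", "trait_heading", "p_value", "date_added", "study_type",
    "odds_ratio", "provisional", "drug_response", "somatic",
]
OMIM_COLUMNS = [
    "gene_id", "trait_heading", "date_added",
    "provisional", "drug_response", "somatic",
]
LINK_COLUMNS = [
    "gene_id", "trait_heading", "source", "channels",
    "date_added", "last_date", "deleterious_r2",
]


def filter_gwas(associations: pd.DataFrame, p_max: float = 1e-8) -> pd.DataFrame:
    """Keep genome-wide significant SNP associations (p_value <= p_max).

    Rows with nonpositive p-values are invalid input.
    """
    p = associations["p_value"].to_numpy(dtype=float)
    if np.any(p <= 0):
        raise ValueError("nonpositive p_value in GWAS association table")
    keep = p <= p_max
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("filter_gwas: dropped %d of %d rows above p=%g",
                    n_dropped, len(associations), p_max)
    return associations.loc[keep].reset_index(drop=True)


def filter_omim(curated: pd.DataFrame) -> pd.DataFrame:
    """Drop provisional, drug-response and somatic-variant curated links."""
    flags = (
        curated["provisional"].astype(bool)
        | curated["drug_response"].astype(bool)
        | curated["somatic"].astype(bool)
    )
    return curated.loc[~flags].reset_index(drop=True)


def ld_expand(
    lead_snps, ld_table: pd.DataFrame, r2_threshold: float = 0.5
) -> pd.DataFrame:
    """Expand lead SNPs to their LD partners at ``r2 >= r2_threshold``.

    ``ld_table`` has columns snp_a, snp_b, r2 and is treated as
    symmetric.  Every lead SNP is also its own partner (r2 = 1).  Returns
    a DataFrame with columns lead_snp, ld_snp, r2.
    """
    if not 0.0 <= r2_threshold <= 1.0:
        raise ValueError("r2_threshold must lie in [0, 1]")
    lead = pd.unique(pd.Series(list(lead_snps)))
    frames = [pd.DataFrame({"lead_snp": lead, "ld_snp": lead, "r2": 1.0})]
    if len(ld_table):
        bad = ~ld_table["r2"].between(0.0, 1.0)
        if bad.any():
            raise ValueError("r2 outside [0, 1] in LD table")
        passing = ld_table.loc[ld_table["r2"] >= r2_threshold]
        for a, b in (("snp_a", "snp_b"), ("snp_b", "snp_a")):
            part = passing.loc[passing[a].isin(lead), [a, b, "r2"]]
            part.columns = ["lead_snp", "ld_snp", "r2"]
            frames.append(part)
    out = pd.concat(frames, ignore_index=True)
    # keep the strongest r2 when a partner is reachable several ways
    out = (
        out.sort_values("r2", ascending=False)
        .drop_duplicates(["lead_snp", "ld_snp"])
        .sort_values(["lead_snp", "ld_snp"])
        .reset_index(drop=True)
    )
    return out


def link_by_distance(
    ld_pairs: pd.DataFrame,
    snp_positions: pd.DataFrame,
    genes: pd.DataFrame,
    window_bp: int = 5000,
) -> pd.DataFrame:
    """Link a lead SNP to a gene when any LD partner lies within
    ``window_bp`` of the gene body (closed interval, same chromosome).

    ``snp_positions``: snp_id, chromosome, position (1-based).
    ``genes``: gene_id, chromosome, start, end (1-based inclusive), ...
    Partners without a known position are skipped with a warning.
    Returns columns lead_snp, gene_id, channel="distance".
    """
    if window_bp < 0:
        raise ValueError("window_bp must be nonnegative")
    placed = ld_pairs.merge(
        snp_positions[["snp_id", "chromosome", "position"]],
        left_on="ld_snp", right_on="snp_id", how="left",
    )
    missing = placed["position"].isna()
    if missing.any():
        logger.warning("link_by_distance: %d LD partners lack positions; skipped",
                       int(missing.sum()))
        placed = placed.loc[~missing]
    hit = placed.merge(genes, on="chromosome", suffixes=("", "_gene"))
    within = (hit["position"] >= hit["start"] - window_bp) & (
        hit["position"] <= hit["end"] + window_bp
    )
    out = hit.loc[within, ["lead_snp", "gene_id"]].drop_duplicates().reset_index(drop=True)
    out["channel"] = "distance"
    return out


def link_by_eqtl(
    ld_pairs: pd.DataFrame, eqtl: pd.DataFrame, p_cutoff: float = 1e-6
) -> pd.DataFrame:
    """Link via expression QTLs: any tissue record with p strictly below
    the cutoff.  ``eqtl`` columns: snp_id, gene_id, tissue, p_value."""
    if p_cutoff <= 0:
        raise ValueError("p_cutoff must be positive")
    sig = eqtl.loc[eqtl["p_value"] < p_cutoff, ["snp_id", "gene_id"]]
    out = ld_pairs.merge(sig, left_on="ld_snp", right_on="snp_id")
    out = out[["lead_snp", "gene_id"]].drop_duplicates().reset_index(drop=True)
    out["channel"] = "eqtl"
    return out


def link_by_dhs(
    ld_pairs: pd.DataFrame, dhs: pd.DataFrame, perm_p_cutoff: float = 0.001
) -> pd.DataFrame:
    """Link via DHS-expression correlation: permutation p at or below the
    cutoff.  ``dhs`` columns: snp_id, gene_id, perm_p."""
    if not 0.0 < perm_p_cutoff <= 1.0:
        raise ValueError("perm_p_cutoff must lie in (0, 1]")
    sig = dhs.loc[dhs["perm_p"] <= perm_p_cutoff, ["snp_id", "gene_id"]]
    out = ld_pairs.merge(sig, left_on="ld_snp", right_on="snp_id")
    out = out[["lead_snp", "gene_id"]].drop_duplicates().reset_index(drop=True)
    out["channel"] = "dhs"
    return out


def _deleterious_r2_by_lead(
    ld_pairs: pd.DataFrame, consequences: pd.DataFrame
) -> pd.Series:
    """Max r2 from each lead SNP to an LD partner with HIGH/MODERATE
    predicted consequence.  ``consequences`` columns: snp_id, severity."""
    deleterious = consequences.loc[
        consequences["severity"].isin(DELETERIOUS_SEVERITIES), "snp_id"
    ]
    hits = ld_pairs.loc[ld_pairs["ld_snp"].isin(set(deleterious))]
    return hits.groupby("lead_snp")["r2"].max()


def assemble_association_set(
    gwas: pd.DataFrame,
    omim: pd.DataFrame,
    genes: pd.DataFrame,
    ld_pairs: pd.DataFrame | None = None,
    snp_positions: pd.DataFrame | None = None,
    eqtl: pd.DataFrame | None = None,
    dhs: pd.DataFrame | None = None,
    consequences: pd.DataFrame | None = None,
    window_bp: int = 5000,
    eqtl_p_cutoff: float = 1e-6,
    dhs_perm_p_cutoff: float = 0.001,
) -> pd.DataFrame:
    """Build the full gene-trait association set A.

    GWAS rows (already significance-filtered) are mapped to genes through
    the distance/eQTL/DHS channels over ``ld_pairs``; curated rows
    (already flag-filtered) map directly with channel "curated".  Links
    to non-protein-coding genes are removed; duplicates on
    (gene, trait, source) collapse with channels accumulated,
    ``date_added`` the earliest and ``last_date`` the latest contributing
    association date, and ``deleterious_r2`` the maximum r2 from any
    contributing lead SNP to a HIGH/MODERATE-consequence LD partner.
    """
    empty = pd.DataFrame(columns=["lead_snp", "gene_id", "channel"])
    channels = []
    if ld_pairs is not None and len(gwas):
        if snp_positions is not None:
            channels.append(
                link_by_distance(ld_pairs, snp_positions, genes, window_bp)
            )
        if eqtl is not None:
            channels.append(link_by_eqtl(ld_pairs, eqtl, eqtl_p_cutoff))
        if dhs is not None:
            channels.append(link_by_dhs(ld_pairs, dhs, dhs_perm_p_cutoff))
    snp_gene = pd.concat(channels, ignore_index=True) if channels else empty

    gwas_links = gwas.merge(snp_gene, left_on="snp_id", right_on="lead_snp")
    gwas_links = gwas_links[
        ["gene_id", "trait_heading", "date_added", "channel", "lead_snp"]
    ].copy()
    gwas_links["source"] = "GWAS"

    if len(gwas_links) and consequences is not None and ld_pairs is not None:
        del_r2 = _deleterious_r2_by_lead(ld_pairs, consequences)
        gwas_links["deleterious_r2"] = gwas_links["lead_snp"].map(del_r2)
    else:
        gwas_links["deleterious_r2"] = np.nan

    omim_links = omim[["gene_id", "trait_heading", "date_added"]].copy()
    omim_links["source"] = "OMIM"
    omim_links["channel"] = "curated"
    omim_links["lead_snp"] = pd.NA
    omim_links["deleterious_r2"] = np.nan

    links = pd.concat([gwas_links, omim_links], ignore_index=True)
    if not len(links):
        return pd.DataFrame(columns=LINK_COLUMNS)

    known = set(genes["gene_id"])
    offenders = sorted(set(links["gene_id"]) - known)
    if offenders:
        raise ValueError(f"links reference unknown gene ids: {offenders}")
    coding = set(genes.loc[genes["protein_coding"].astype(bool), "gene_id"])
    links = links.loc[links["gene_id"].isin(coding)]

    collapsed = (
        links.groupby(["gene_id", "trait_heading", "source"], as_index=False)
        .agg(
            channels=("channel", lambda c: ",".join(sorted(set(c)))),
            date_added=("date_added", "min"),
            last_date=("date_added", "max"),
            deleterious_r2=("deleterious_r2", "max"),
        )
    )
    return collapsed[LINK_COLUMNS].sort_values(
        ["gene_id", "trait_heading", "source"]
    ).reset_index(drop=True)


def deleterious_subset(links: pd.DataFrame, r2_min: float = 0.9) -> pd.DataFrame:
    """GWAS links restricted to those in high LD with a predicted
    deleterious variant (deleterious_r2 >= r2_min, inclusive); curated
    links pass through unchanged."""
    if not 0.0 <= r2_min <= 1.0:
        raise ValueError("r2_min must lie in [0, 1]")
    is_gwas = links["source"] == "GWAS"
    keep = ~is_gwas | (links["deleterious_r2"].fillna(-1.0) >= r2_min)
    return links.loc[keep].reset_index(drop=True)
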