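"""Readers and writers for the plain-TSV dialects the toolchain uses.

Every table is tab-separated with a header row.  Readers validate the
required columns and return pandas DataFrames; boolean flag columns
accept true/false, 1/0, yes/no.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .ontology import OntologyGraph
from .pipeline import DrugBundle

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False,
             "yes": True, "no": False}

REQUIRED = {
    "edges": ["child", "parent"],
    "tree_numbers": ["term", "tree_number"],
    "overrides": ["term_a", "term_b", "similarity"],
    "gwas": ["snp_id", "trait_heading", "p_value", "date_added"],
    "omim": ["gene_id", "trait_heading", "date_added"],
    "ld": ["snp_a", "snp_b", "r2"],
    "snp_positions": ["snp_id", "chromosome", "position"],
    "genes": ["gene_id", "chromosome", "start", "end", "protein_coding"],
    "eqtl": ["snp_id", "gene_id", "p_value"],
    "dhs": ["snp_id", "gene_id", "perm_p"],
    "consequences": ["snp_id", "severity"],
    "links": ["gene_id", "trait_heading", "source"],
    "pairs": ["gene_id", "indication", "latest_phase", "approved", "active"],
    "evidence": ["gene_id", "indication", "source", "e_c", "has_assoc"],
    "drugs": ["drug_id", "global_status", "is_active"],
    "drug_targets": ["drug_id", "gene_id", "non_human", "xmhc"],
    "drug_indications": ["drug_id", "indication"],
    "country_status": ["drug_id", "indication", "country", "status"],
    "events": ["drug_id", "indication", "event_phrase"],
    "clinical_details": ["drug_id", "indication", "detail_phrase"],
}

_FLAG_COLUMNS = ("provisional", "drug_response", "somatic", "protein_coding",
                 "is_active", "non_human", "xmhc", "approved", "active")


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read one TSV, checking the column contract for ``kind``."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    required = REQUIRED.get(kind, [])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing} for {kind!r}")
    for col in _FLAG_COLUMNS:
        if col in df.columns and df[col].dtype == object:
            df[col] = df[col].astype(str).str.lower().map(_BOOL_MAP)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_ontology(path: str | Path, tree_numbers: bool = False) -> OntologyGraph:
    """Edge-list TSV (child, parent) or tree-number TSV (term, tree_number)."""
    if tree_numbers:
        table = read_table(path, "tree_numbers")
        return OntologyGraph.from_tree_numbers(table)
    table = read_table(path, "edges")
    return OntologyGraph.from_edges(
        (p, c) for c, p in table[["child", "parent"]].itertuples(index=False)
    )


def read_drug_bundle(directory: str | Path) -> DrugBundle:
    """Read the six pipeline tables from one snapshot directory."""
    directory = Path(directory)
    tables = {
        name: read_table(directory / f"{name}.tsv", name)
        for name in DrugBundle.TABLE_NAMES
    }
    return DrugBundle(**tables)
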