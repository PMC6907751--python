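"""Drug-pipeline assembly: latest historical phase per drug-indication,
US/EU approval flags, target exclusions, and collapse to target-indication
pairs.

Phase codes are ordinal: 0 Preclinical, 1-3 clinical trial phases,
4 US/EU Approved; ``None`` marks an unknown latest phase (kept distinct
from 0 because downstream analyses treat unknown-phase pairs
differently: excluded from two-by-two progression tables, retained as
unapproved in the approval model).

A drug bundle is a set of plain tables:

* drugs: drug_id, global_status, is_active, first_added
* drug_targets: drug_id, gene_id, non_human, xmhc
* drug_indications: drug_id, indication
* country_status: drug_id, indication, country, status
* events: drug_id, indication, date, event_phrase
* clinical_details: drug_id, indication, detail_phrase
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

PHASE_LABELS = {0: "Preclinical", 1: "Phase I", 2: "Phase II",
                3: "Phase III", 4: "Approved"}

#: Default mapping from status/event/detail phrases to ordinal phases.
#: Matching is case-insensitive on the whole phrase; longest-phrase rules
#: are listed explicitly so "phase iii" never matches as "phase i".
DEFAULT_PHASE_TERMS: dict[str, int] = {
    "preclinical": 0,
    "phase i": 1,
    "phase i trial": 1,
    "phase ii": 2,
    "phase ii trial": 2,
    "phase iii": 3,
    "phase iii trial": 3,
    "approved": 4,
    "registered": 4,
    "launched": 4,
}

US_EU_COUNTRIES = frozenset({"US", "EU"})


def phase_from_phrase(
    phrase: str, vocabulary: dict[str, int] | None = None
) -> int | None:
    """Ordinal phase implied by a free-text phrase, or None."""
    vocab = DEFAULT_PHASE_TERMS if vocabulary is None else vocabulary
    return vocab.get(str(phrase).strip().lower())


@dataclass
class DrugBundle:
    """The six pipeline tables for one snapshot."""

    drugs: pd.DataFrame
    drug_targets: pd.DataFrame
    drug_indications: pd.DataFrame
    country_status: pd.DataFrame
    events: pd.DataFrame
    clinical_details: pd.DataFrame
    phase_vocabulary: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_PHASE_TERMS))

    TABLE_NAMES = (
        "drugs", "drug_targets", "drug_indications",
        "country_status", "events", "clinical_details",
    )

    def indications_of(self, drug_id: str) -> list[str]:
        sub = self.drug_indications
        return sub.loc[sub["drug_id"] == drug_id, "indication"].tolist()


def _max_phase(phrases, vocabulary) -> int | None:
    phases = [phase_from_phrase(p, vocabulary) for p in phrases]
    phases = [p for p in phases if p is not None]
    return max(phases) if phases else None


def assign_latest_phase(
    bundle: DrugBundle, drug_id: str, indication: str
) -> tuple[int | None, str]:
    """Latest historical phase for one drug-indication, with provenance.

    Precedence: (1) country status, for single-indication or preclinical
    drugs; (2) the most advanced phase implied by dated events for the
    indication; (3) clinical-details phrases as a last-resort fallback
    (that field may describe planned trials).  Returns (phase, source)
    where source in {"country", "event", "clinical_details", "none"}.
    """
    if indication not in bundle.indications_of(drug_id):
        raise ValueError(f"{indication!r} is not an indication of {drug_id!r}")
    vocab = bundle.phase_vocabulary
    drug_row = bundle.drugs.loc[bundle.drugs["drug_id"] == drug_id]
    global_status = drug_row["global_status"].iloc[0] if len(drug_row) else ""
    single_indication = len(bundle.indications_of(drug_id)) == 1
    is_preclinical = phase_from_phrase(global_status, vocab) == 0

    if single_indication or is_preclinical:
        cs = bundle.country_status
        rows = cs.loc[(cs["drug_id"] == drug_id) & (cs["indication"] == indication)]
        phase = _max_phase(rows["status"], vocab)
        if phase is not None:
            return phase, "country"

    ev = bundle.events
    rows = ev.loc[(ev["drug_id"] == drug_id) & (ev["indication"] == indication)]
    phase = _max_phase(rows["event_phrase"], vocab)
    if phase is not None:
        return phase, "event"

    cd = bundle.clinical_details
    rows = cd.loc[(cd["drug_id"] == drug_id) & (cd["indication"] == indication)]
    phase = _max_phase(rows["detail_phrase"], vocab)
    if phase is not None:
        return phase, "clinical_details"
    return None, "none"


def approval_flag(bundle: DrugBundle, drug_id: str, indication: str) -> int:
    """1 iff the drug is approved in the US or EU and the indication is
    among its approved indications (in any country).

    When approvals are partial across countries this deliberately
    over-assigns, matching the indication-level granularity of the
    source data.
    """
    cs = bundle.country_status
    rows = cs.loc[cs["drug_id"] == drug_id]
    vocab = bundle.phase_vocabulary
    approved_status = rows["status"].map(lambda s: phase_from_phrase(s, vocab) == 4)
    us_eu_approved = bool(
        (approved_status & rows["country"].isin(US_EU_COUNTRIES)).any()
    )
    indication_approved = bool(
        (approved_status & (rows["indication"] == indication)).any()
    )
    return int(us_eu_approved and indication_approved)


def apply_target_exclusions(bundle: DrugBundle, genes: pd.DataFrame) -> DrugBundle:
    """Drop drugs with non-human or xMHC-flagged targets, or with targets
    that are not protein-coding genes."""
    dt = bundle.drug_targets
    coding = set(genes.loc[genes["protein_coding"].astype(bool), "gene_id"])
    bad_rows = (
        dt["non_human"].astype(bool)
        | dt["xmhc"].astype(bool)
        | ~dt["gene_id"].isin(coding)
    )
    bad_drugs = set(dt.loc[bad_rows, "drug_id"])
    keep = lambda df: df.loc[~df["drug_id"].isin(bad_drugs)].reset_index(drop=True)
    return DrugBundle(
        drugs=keep(bundle.drugs),
        drug_targets=keep(bundle.drug_targets),
        drug_indications=keep(bundle.drug_indications),
        country_status=keep(bundle.country_status),
        events=keep(bundle.events),
        clinical_details=keep(bundle.clinical_details),
        phase_vocabulary=bundle.phase_vocabulary,
    )


def collapse_to_pairs(bundle: DrugBundle, snapshot_label: str = "") -> pd.DataFrame:
    """Collapse drugs to one row per (gene target, indication).

    latest_phase is the maximum assigned phase over contributing drugs
    (unknowns ignored unless every drug is unknown, then <NA>);
    approved_us_eu and has_active_drug are logical ORs.  Approval forces
    phase 4.  Output columns: gene_id, indication, latest_phase,
    approved, active, snapshot.
    """
    active_by_drug = dict(
        zip(bundle.drugs["drug_id"], bundle.drugs["is_active"].astype(bool))
    )
    rows = []
    di = bundle.drug_indications.merge(bundle.drug_targets[["drug_id", "gene_id"]],
                                       on="drug_id")
    for rec in di.itertuples(index=False):
        phase, phase_source = assign_latest_phase(bundle, rec.drug_id, rec.indication)
        approved = approval_flag(bundle, rec.drug_id, rec.indication)
        if approved and (phase is None or phase < 4):
            if phase is not None:
                logger.warning(
                    "approved %s/%s carries phase %s; approval wins",
                    rec.drug_id, rec.indication, phase,
                )
            phase = 4
        rows.append((rec.gene_id, rec.indication, phase, approved,
                     active_by_drug.get(rec.drug_id, False)))
    per_drug = pd.DataFrame(
        rows, columns=["gene_id", "indication", "phase", "approved", "active"]
    )
    if not len(per_drug):
        out = pd.DataFrame(
            columns=["gene_id", "indication", "latest_phase", "approved", "active"]
        )
        out["snapshot"] = pd.Series(dtype=object)
        return out
    collapsed = (
        per_drug.groupby(["gene_id", "indication"], as_index=False)
        .agg(
            latest_phase=("phase", lambda p: p.dropna().max() if p.notna().any() else None),
            approved=("approved", "max"),
            active=("active", "max"),
        )
    )
    collapsed["latest_phase"] = collapsed["latest_phase"].astype("Int64")
    collapsed["snapshot"] = snapshot_label
    return collapsed.sort_values(["gene_id", "indication"]).reset_index(drop=True)
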