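"""Synthetic inputs with known generating parameters.

Emulates every table the analysis consumes: a random rooted-DAG trait
vocabulary, a gene universe, dated SNP-level (GWAS-style) and gene-level
(curated, OMIM-style) association tables with LD / eQTL / DHS /
consequence side tables, and drug-pipeline bundles over two snapshots
whose approval outcomes are sampled from the package's own logistic
approval model at known parameter values.

Continuous evidence for simulated pairs is computed through the real
ontology and evidence-scoring code, so parameter-recovery experiments
isolate the statistical stages; the ontology code itself is checked
against independent brute-force oracles elsewhere.  Generating
parameters default to the study conditions: intercept -2.2 (a ~10%
baseline approval rate), evidence polynomial degree 2, association
dates straddling the 2013 cut dates that define the new-genetic
validation split.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gene_links
from .approval_model import DesignMatrix, build_design
from .evidence import score_pairs
from .ontology import OntologyGraph, build_similarity_function

GWAS_CUT_DATE = "2013-05-21"
OMIM_CUT_DATE = "2013-10-01"


@dataclass(frozen=True)
class OntologyConfig:
    n_terms: int = 60
    max_children: int = 4
    depth: int = 5
    cross_link_rate: float = 0.1


@dataclass(frozen=True)
class GeneConfig:
    n: int = 300
    protein_coding_fraction: float = 0.9
    n_chromosomes: int = 5


@dataclass(frozen=True)
class AssociationConfig:
    n_gwas: int = 200
    n_omim: int = 120
    date_start: str = "2009-01-01"
    date_end: str = "2018-01-01"
    deleterious_fraction: float = 0.3
    ld_partners_mean: float = 2.0
    eqtl_fraction: float = 0.3
    dhs_fraction: float = 0.2


@dataclass(frozen=True)
class PipelineConfig:
    n_pairs: int = 1500
    active_fraction: float = 0.1
    unknown_phase_fraction: float = 0.05
    phase_marginals: tuple[float, ...] = (0.35, 0.25, 0.2, 0.2)  # phases 0..3 if unapproved
    progression_fraction: float = 0.2
    absent_from_old_fraction: float = 0.25
    snapshot_old: str = "2013"
    snapshot_new: str = "2018"


@dataclass(frozen=True)
class TruthConfig:
    alpha: float = -2.2
    beta_pattern: tuple[float, ...] = (0.4, -0.3, 0.2)
    gamma: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {"GWAS": (0.2, 0.5, -0.3), "OMIM": (0.5, 0.8, -0.3)}
    )


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    ontology: OntologyConfig = OntologyConfig()
    genes: GeneConfig = GeneConfig()
    associations: AssociationConfig = AssociationConfig()
    pipeline: PipelineConfig = PipelineConfig()
    truth: TruthConfig = TruthConfig()

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        """Build from a plain mapping (e.g. parsed YAML); nested section
        mappings become the corresponding sub-configs, lists become
        tuples."""
        sections = {"ontology": OntologyConfig, "genes": GeneConfig,
                    "associations": AssociationConfig,
                    "pipeline": PipelineConfig, "truth": TruthConfig}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        kwargs = {}
        for name, value in raw.items():
            sub_cls = sections.get(name)
            if sub_cls is not None and isinstance(value, dict):
                value = dict(value)
                if "gamma" in value:
                    value["gamma"] = {k: tuple(g) for k, g in value["gamma"].items()}
                value = sub_cls(**{k: tuple(x) if isinstance(x, list) else x
                                   for k, x in value.items()})
            kwargs[name] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


@dataclass
class GroundTruth:
    """The generating parameters and per-pair latent quantities."""

    alpha: float
    beta: dict[str, float]
    gamma: dict[str, tuple[float, ...]]
    e_c: pd.DataFrame          # gene_id, indication, source, e_c, has_assoc
    eta: np.ndarray            # per-pair total evidence contribution
    approval_probability: np.ndarray

    def to_json(self) -> str:
        return json.dumps({
            "alpha": self.alpha,
            "beta": self.beta,
            "gamma": {k: list(v) for k, v in self.gamma.items()},
            "eta": self.eta.tolist(),
            "approval_probability": self.approval_probability.tolist(),
        }, indent=1)


# ---------------------------------------------------------------------------
# generators


def generate_ontology(config: OntologyConfig, rng: np.random.Generator) -> OntologyGraph:
    """Random rooted DAG: a depth-capped random tree plus cross-links
    (each giving a node a second parent) to exercise multi-path MICA
    search.  Deterministic under the generator's state."""
    if config.n_terms < 2:
        raise ValueError("n_terms must be at least 2")
    if config.depth > config.n_terms:
        raise ValueError("depth cannot exceed n_terms")
    terms = [f"T{i:03d}" for i in range(config.n_terms)]
    root = terms[0]
    depth_of = {root: 0}
    children_of: dict[str, int] = {root: 0}
    edges = []
    for term in terms[1:]:
        candidates = [
            t for t in depth_of
            if depth_of[t] < config.depth and children_of[t] < config.max_children
        ]
        if not candidates:
            candidates = [root]
        parent = candidates[rng.integers(len(candidates))]
        edges.append((parent, term))
        depth_of[term] = depth_of[parent] + 1
        children_of[parent] = children_of.get(parent, 0) + 1
        children_of.setdefault(term, 0)
    # cross links: extra parent chosen among earlier terms (keeps it acyclic)
    order = {t: i for i, t in enumerate(terms)}
    existing = set(edges)
    for term in terms[2:]:
        if rng.random() < config.cross_link_rate:
            earlier = terms[: order[term]]
            extra = earlier[rng.integers(len(earlier))]
            if (extra, term) not in existing and extra != term:
                edges.append((extra, term))
                existing.add((extra, term))
    return OntologyGraph.from_edges(edges, root=root)


def generate_genes(config: GeneConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Gene universe: id, chromosome, 1-based body coordinates,
    protein-coding flag, RVIS percentile (some missing), first
    development date."""
    n = config.n
    chrom = rng.integers(1, config.n_chromosomes + 1, size=n)
    start = rng.integers(1, 5_000_000, size=n)
    length = rng.integers(2_000, 200_000, size=n)
    coding = rng.random(n) < config.protein_coding_fraction
    rvis = np.round(rng.uniform(0, 100, size=n), 2)
    rvis[rng.random(n) < 0.1] = np.nan
    dev_year = rng.integers(1990, 2016, size=n)
    return pd.DataFrame({
        "gene_id": [f"G{i:04d}" for i in range(n)],
        "chromosome": chrom.astype(str),
        "start": start,
        "end": start + length,
        "protein_coding": coding,
        "rvis_percentile": rvis,
        "first_development_date": [f"{y}-01-01" for y in dev_year],
    })


def _random_dates(rng, n, start: str, end: str) -> list[str]:
    lo = pd.Timestamp(start).value // 10**9
    hi = pd.Timestamp(end).value // 10**9
    secs = rng.integers(lo, hi, size=n)
    return [pd.Timestamp(s, unit="s").strftime("%Y-%m-%d") for s in secs]


@dataclass
class AssociationTables:
    gwas: pd.DataFrame
    omim: pd.DataFrame
    ld: pd.DataFrame
    snp_positions: pd.DataFrame
    eqtl: pd.DataFrame
    dhs: pd.DataFrame
    consequences: pd.DataFrame


def generate_associations(
    config: AssociationConfig,
    ontology: OntologyGraph,
    genes: pd.DataFrame,
    rng: np.random.Generator,
) -> AssociationTables:
    """Dated association tables plus SNP side tables.

    Each GWAS lead SNP is placed near a random gene (so the distance
    channel links them), given LD partners (always including itself in
    the LD-expansion sense), and a configured fraction receives a
    high-r2 partner with HIGH/MODERATE predicted consequence to
    exercise the deleterious-variant subset.  Dates are uniform over
    [date_start, date_end], straddling the validation cut dates.
    """
    traits = sorted(ontology.terms - {ontology.root})
    n = config.n_gwas
    gene_rows = genes.sample(n=n, replace=True, random_state=int(rng.integers(2**31)))
    lead_ids = [f"rs{i:05d}" for i in range(n)]
    positions = []
    for (row, snp) in zip(gene_rows.itertuples(index=False), lead_ids):
        offset = int(rng.integers(-4000, max(row.end - row.start, 1) + 4000))
        positions.append((snp, row.chromosome, max(1, row.start + offset)))
    p_exponent = rng.uniform(8.0, 20.0, size=n)
    # a tail of sub-threshold rows exercises the significance filter
    weak = rng.random(n) < 0.1
    p_exponent[weak] = rng.uniform(5.0, 7.9, size=int(weak.sum()))
    gwas = pd.DataFrame({
        "snp_id": lead_ids,
        "trait_heading": rng.choice(traits, size=n),
        "p_value": 10.0 ** (-p_exponent),
        "date_added": _random_dates(rng, n, config.date_start, config.date_end),
        "study_type": rng.choice(["case_control", "quantitative", "other"], size=n,
                                 p=[0.5, 0.4, 0.1]),
        "odds_ratio": np.round(np.exp(rng.normal(0.1, 0.2, size=n)), 3),
        "provisional": False,
        "drug_response": False,
        "somatic": False,
    })

    ld_rows, eqtl_rows, dhs_rows, cons_rows = [], [], [], []
    partner_counter = 0
    for i, snp in enumerate(lead_ids):
        chrom = positions[i][1]
        pos = positions[i][2]
        n_partners = rng.poisson(config.ld_partners_mean)
        deleterious_here = rng.random() < config.deleterious_fraction
        for k in range(n_partners + (1 if deleterious_here else 0)):
            partner = f"ld{partner_counter:06d}"
            partner_counter += 1
            is_deleterious = deleterious_here and k == n_partners
            r2 = float(rng.uniform(0.9, 1.0)) if is_deleterious else float(
                np.round(rng.uniform(0.2, 1.0), 3)
            )
            ld_rows.append((snp, partner, r2))
            positions.append((partner, chrom, max(1, pos + int(rng.integers(-50_000, 50_000)))))
            if is_deleterious:
                cons_rows.append((partner, str(rng.choice(["HIGH", "MODERATE"]))))
            elif rng.random() < 0.1:
                cons_rows.append((partner, str(rng.choice(["LOW", "MODIFIER"]))))
            gene_id = gene_rows.iloc[i]["gene_id"]
            if rng.random() < config.eqtl_fraction:
                eqtl_rows.append((partner, gene_id, "tissue_a",
                                  10.0 ** -float(rng.uniform(6.1, 15.0))))
            if rng.random() < config.dhs_fraction:
                dhs_rows.append((partner, gene_id, 0.001))

    m = config.n_omim
    omim_genes = genes.sample(n=m, replace=True,
                              random_state=int(rng.integers(2**31)))
    flags = rng.random((m, 3)) < 0.05
    omim = pd.DataFrame({
        "gene_id": omim_genes["gene_id"].to_numpy(),
        "trait_heading": rng.choice(traits, size=m),
        "date_added": _random_dates(rng, m, config.date_start, config.date_end),
        "provisional": flags[:, 0],
        "drug_response": flags[:, 1],
        "somatic": flags[:, 2],
    })

    return AssociationTables(
        gwas=gwas,
        omim=omim,
        ld=pd.DataFrame(ld_rows, columns=["snp_a", "snp_b", "r2"]),
        snp_positions=pd.DataFrame(positions,
                                   columns=["snp_id", "chromosome", "position"]),
        eqtl=pd.DataFrame(eqtl_rows,
                          columns=["snp_id", "gene_id", "tissue", "p_value"]),
        dhs=pd.DataFrame(dhs_rows, columns=["snp_id", "gene_id", "perm_p"]),
        consequences=pd.DataFrame(cons_rows, columns=["snp_id", "severity"]),
    )


def assemble_links(tables: AssociationTables, genes: pd.DataFrame,
                   r2_threshold: float = 0.5) -> pd.DataFrame:
    """Run the real mapping pipeline on the synthetic tables."""
    gwas = gene_links.filter_gwas(tables.gwas)
    omim = gene_links.filter_omim(tables.omim)
    ld_pairs = gene_links.ld_expand(gwas["snp_id"], tables.ld, r2_threshold)
    return gene_links.assemble_association_set(
        gwas, omim, genes,
        ld_pairs=ld_pairs, snp_positions=tables.snp_positions,
        eqtl=tables.eqtl, dhs=tables.dhs, consequences=tables.consequences,
    )


# ---------------------------------------------------------------------------
# approval-model dataset


@dataclass
class ModelDataset:
    """Everything needed to fit and score the approval model."""

    pairs: pd.DataFrame        # gene_id, indication, covariates, y, approved, active
    evidence: pd.DataFrame     # long table from score_pairs
    design: DesignMatrix
    y: np.ndarray
    truth: GroundTruth
    links: pd.DataFrame
    similarity: "object"


def simulate_model_dataset(
    config: SimulationConfig,
    n_pairs: int | None = None,
) -> ModelDataset:
    """Sample target-indication pairs and their approval outcomes from
    the generating logistic model.

    Pairs draw a random coding gene and indication heading; continuous
    evidence is computed through the real similarity/evidence code
    against the synthetic association set; covariates are two
    categorical class factors plus development time and RVIS.  The
    linear predictor uses the generating parameters on the standardized
    scale (the scale on which the model is fit), and y ~ Bernoulli.
    """
    rng = np.random.default_rng(config.seed)
    ontology = generate_ontology(config.ontology, rng)
    genes = generate_genes(config.genes, rng)
    tables = generate_associations(config.associations, ontology, genes, rng)
    links = assemble_links(tables, genes)
    s_t = build_similarity_function(ontology)

    n = n_pairs if n_pairs is not None else config.pipeline.n_pairs
    coding = genes.loc[genes["protein_coding"]]
    traits = sorted(ontology.terms - {ontology.root})
    pairs = pd.DataFrame({
        "gene_id": rng.choice(coding["gene_id"].to_numpy(), size=n),
        "indication": rng.choice(traits, size=n),
    })
    pairs = pairs.drop_duplicates().reset_index(drop=True)
    n = len(pairs)
    pairs["indication_class"] = rng.choice(["onc", "cardio", "neuro", "immuno"], size=n)
    pairs["target_class"] = rng.choice(["enzyme", "receptor", "channel"], size=n)
    pairs = pairs.merge(
        genes[["gene_id", "rvis_percentile", "first_development_date"]],
        on="gene_id", how="left",
    )
    pairs["dev_time_years"] = 2018.0 - pairs["first_development_date"].str.slice(0, 4).astype(float)

    evidence = score_pairs(pairs, links, s_t)
    design = build_design(
        pairs,
        categorical=["indication_class", "target_class"],
        continuous=["dev_time_years", "rvis_percentile"],
        evidence=evidence,
        rare_level_min=20,
    )

    truth_cfg = config.truth
    beta_pattern = np.asarray(truth_cfg.beta_pattern, dtype=float)
    beta = (
        np.resize(beta_pattern, design.d) if design.d else np.empty(0)
    )
    eta = np.zeros(n)
    for source, gamma in truth_cfg.gamma.items():
        if source not in design.evidence:
            continue
        blk = design.evidence[source]
        g = np.asarray(gamma, dtype=float)
        eta += blk.exists * (np.vander(blk.z, len(g), increasing=True) @ g)
    logits = truth_cfg.alpha + design.X @ beta + eta
    prob = 1.0 / (1.0 + np.exp(-logits))
    y = (rng.random(n) < prob).astype(int)

    pairs["y"] = y
    pairs["approved"] = y
    pairs["active"] = False
    truth = GroundTruth(
        alpha=truth_cfg.alpha,
        beta=dict(zip(design.columns, beta.tolist())),
        gamma={k: tuple(v) for k, v in truth_cfg.gamma.items()},
        e_c=evidence,
        eta=eta,
        approval_probability=prob,
    )
    return ModelDataset(pairs=pairs, evidence=evidence, design=design, y=y,
                        truth=truth, links=links, similarity=s_t)


# ---------------------------------------------------------------------------
# drug bundles


def generate_pipeline(
    config: SimulationConfig,
) -> tuple["object", "object", ModelDataset]:
    """Drug-record bundles for two snapshots realizing the sampled pairs.

    Approved pairs get a US-approved drug (phase 4); unapproved pairs
    get a drug whose latest phase is sampled from the configured
    marginals, realized through country status, dated events, or a
    clinical-details phrase so every precedence branch of phase
    assignment is exercised.  A fraction of unapproved drugs is marked
    active.  The old snapshot demotes a fraction of pairs by one phase
    (those pairs have progressed by the new snapshot) and omits another
    fraction entirely (the new-pipeline set).
    """
    from .pipeline import DrugBundle, PHASE_LABELS

    ds = simulate_model_dataset(config)
    rng = np.random.default_rng(config.seed + 1)
    pc = config.pipeline
    pairs = ds.pairs

    n = len(pairs)
    marginals = np.asarray(pc.phase_marginals, dtype=float)
    marginals = marginals / marginals.sum()
    sampled_phase = rng.choice(4, size=n, p=marginals)
    phase = np.where(pairs["approved"] == 1, 4, sampled_phase)
    unknown = (rng.random(n) < pc.unknown_phase_fraction) & (pairs["approved"] == 0)
    active = (rng.random(n) < pc.active_fraction) & (pairs["approved"] == 0)
    pairs = pairs.assign(latest_phase=phase, unknown=unknown, active=active)

    route = rng.choice(["country", "event", "details"], size=n, p=[0.6, 0.3, 0.1])

    def build_bundle(pair_table: pd.DataFrame, demote: np.ndarray) -> DrugBundle:
        """``pair_table`` keeps the original positional index so routes,
        demotions and drug ids stay aligned across snapshots."""
        drugs, targets, indications, country, events, details = [], [], [], [], [], []
        for row in pair_table.itertuples(index=True):
            i = row.Index
            drug_id = f"D{i:05d}"
            ph = max(0, int(row.latest_phase) - int(demote[i]))
            approved = row.approved == 1 and ph == 4
            label = PHASE_LABELS[ph]
            status = label if not approved else "Approved"
            global_status = status if row.active else "Discontinued"
            drugs.append((drug_id, global_status, bool(row.active), "2010-01-01"))
            targets.append((drug_id, row.gene_id, False, False))
            indications.append((drug_id, row.indication))
            if row.unknown:
                continue  # no phase-bearing fields at all
            if approved:
                country.append((drug_id, row.indication, "US", "Approved"))
            elif route[i] == "country":
                country.append((drug_id, row.indication, "US", label))
            elif route[i] == "event":
                events.append((drug_id, row.indication, "2015-06-01",
                               f"{label} trial" if ph > 0 else "Preclinical"))
            else:
                details.append((drug_id, row.indication, label))
        return DrugBundle(
            drugs=pd.DataFrame(drugs, columns=["drug_id", "global_status",
                                               "is_active", "first_added"]),
            drug_targets=pd.DataFrame(targets, columns=["drug_id", "gene_id",
                                                        "non_human", "xmhc"]),
            drug_indications=pd.DataFrame(indications,
                                          columns=["drug_id", "indication"]),
            country_status=pd.DataFrame(country, columns=["drug_id", "indication",
                                                          "country", "status"]),
            events=pd.DataFrame(events, columns=["drug_id", "indication", "date",
                                                 "event_phrase"]),
            clinical_details=pd.DataFrame(details, columns=["drug_id", "indication",
                                                            "detail_phrase"]),
        )

    bundle_new = build_bundle(pairs, np.zeros(n, dtype=int))

    in_old = rng.random(n) >= pc.absent_from_old_fraction
    demote_old = (
        (rng.random(n) < pc.progression_fraction)
        & (pairs["latest_phase"].to_numpy() > 0)
    ).astype(int)
    bundle_old = build_bundle(pairs.loc[in_old], demote_old)

    return bundle_old, bundle_new, ds


# ---------------------------------------------------------------------------
# serialization


def write_simulation(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Materialize the synthetic inputs as the TSV dialects the rest of
    the toolchain reads, plus truth.json.  Returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    ontology = generate_ontology(config.ontology, rng)
    genes = generate_genes(config.genes, rng)
    tables = generate_associations(config.associations, ontology, genes, rng)
    bundle_old, bundle_new, ds = generate_pipeline(config)

    paths: dict[str, Path] = {}

    def save(name: str, df: pd.DataFrame) -> None:
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p

    edges = pd.DataFrame(
        [(c, p) for p, c in ontology.graph.edges], columns=["child", "parent"]
    )
    save("ontology_edges", edges)
    save("genes", genes)
    save("gwas", tables.gwas)
    save("omim", tables.omim)
    save("ld", tables.ld)
    save("snp_positions", tables.snp_positions)
    save("eqtl", tables.eqtl)
    save("dhs", tables.dhs)
    save("consequences", tables.consequences)
    for label, bundle in (("old", bundle_old), ("new", bundle_new)):
        sub = outdir / f"snapshot_{label}"
        sub.mkdir(exist_ok=True)
        for tname in bundle.TABLE_NAMES:
            p = sub / f"{tname}.tsv"
            getattr(bundle, tname).to_csv(p, sep="\t", index=False)
            paths[f"{label}/{tname}"] = p
    truth_path = outdir / "truth.json"
    truth_path.write_text(ds.truth.to_json())
    paths["truth"] = truth_path
    return paths
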