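"""End-to-end orchestration: simulate -> similarity -> map-genes ->
score -> assemble -> partition -> riskratio -> fit -> curve, with a
manifest and a static markdown report.

Each stage reads and writes plain files in the run directory, so any
stage's output can be inspected or regenerated in isolation.  The
manifest records the configuration, seeds and a SHA-256 digest of every
artifact; deterministic stages reproduce identical digests under the
same seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .approval_model import ModelSpec, build_design, fit_approval_model, odds_ratio_curve, select_model_universe, waic
from .evidence import score_pairs
from .ontology import build_similarity_function, pairwise_similarity_table
from .pipeline import apply_target_exclusions, collapse_to_pairs
from .progression import partition_validation_sets, progression_risk_ratio
from .simulate import GWAS_CUT_DATE, OMIM_CUT_DATE, SimulationConfig, generate_pipeline, write_simulation

logger = logging.getLogger(__name__)

STAGES = ("simulate", "similarity", "map_genes", "assemble", "score",
          "partition", "riskratio", "fit", "curve", "report")

DEPENDENCIES = {
    "similarity": ("simulate",),
    "map_genes": ("simulate",),
    "assemble": ("simulate",),
    "score": ("map_genes", "assemble", "similarity"),
    "partition": ("assemble", "map_genes"),
    "riskratio": ("score", "partition"),
    "fit": ("score", "assemble"),
    "curve": ("fit",),
    "report": ("riskratio", "curve"),
}

EXIT_VALIDATION, EXIT_CONVERGENCE, EXIT_UNDEFINED = 2, 3, 4


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str, exit_code: int = 1):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage
        self.exit_code = exit_code


@dataclass
class RunConfig:
    outdir: str = "runs/run"
    seed: int = 0
    skip: tuple[str, ...] = ()
    simulation: dict = field(default_factory=dict)
    cutoff: float = 0.7
    min_assoc: int = 5
    r2_threshold: float = 0.5
    eqtl_p_cutoff: float = 1e-6
    dhs_perm_p_cutoff: float = 0.001
    deleterious_r2: float = 0.9
    n_boot: int = 2000
    transitions: tuple[tuple[int, int], ...] = ((1, 4), (2, 3), (1, 2), (3, 4))
    degree: int = 2
    chains: int = 4
    gwas_cut_date: str = GWAS_CUT_DATE
    omim_cut_date: str = OMIM_CUT_DATE

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "transitions" in raw:
            raw["transitions"] = tuple(tuple(t) for t in raw["transitions"])
        if "skip" in raw:
            raw["skip"] = tuple(raw["skip"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all non-skipped stages in dependency order; returns the
    manifest (also written to manifest.json in the run directory)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    done: set[str] = set()
    artifacts: dict[str, str] = {}
    sim_cfg = SimulationConfig.from_dict({"seed": config.seed, **config.simulation})
    state: dict = {}

    def register(name: str, path: Path) -> None:
        artifacts[name] = _sha256(path)

    for stage in STAGES:
        if stage in config.skip:
            logger.info("skipping stage %s", stage)
            continue
        missing = [d for d in DEPENDENCIES.get(stage, ()) if d not in done]
        if missing:
            raise StageError(stage, f"requires skipped/failed stage(s) {missing}")
        try:
            _run_stage(stage, config, sim_cfg, outdir, state, register)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-tag with the stage name
            code = {"ConvergenceError": EXIT_CONVERGENCE,
                    "UndefinedRiskRatio": EXIT_UNDEFINED,
                    "ValueError": EXIT_VALIDATION}.get(type(exc).__name__, 1)
            raise StageError(stage, str(exc), code) from exc
        done.add(stage)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in dataclasses.asdict(config).items()},
        "stages_complete": sorted(done),
        "artifacts": artifacts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def _run_stage(stage, config: RunConfig, sim_cfg, outdir: Path, state, register):
    if stage == "simulate":
        paths = write_simulation(sim_cfg, outdir / "sim")
        for name, p in paths.items():
            register(f"sim/{name}", p)
        bundle_old, bundle_new, ds = generate_pipeline(sim_cfg)
        state.update(bundle_old=bundle_old, bundle_new=bundle_new, dataset=ds)

    elif stage == "similarity":
        ds = state["dataset"]
        state["s_t"] = ds.similarity
        table = pairwise_similarity_table(ds.similarity)
        register("similarity", io.write_table(table, outdir / "similarity.tsv"))

    elif stage == "map_genes":
        ds = state["dataset"]
        state["links"] = ds.links
        register("links", io.write_table(ds.links, outdir / "links.tsv"))

    elif stage == "assemble":
        genes = io.read_table(outdir / "sim" / "genes.tsv", "genes")
        pairs = {}
        for label in ("old", "new"):
            bundle = apply_target_exclusions(state[f"bundle_{label}"], genes)
            pairs[label] = collapse_to_pairs(bundle, snapshot_label=label)
            register(f"pairs_{label}",
                     io.write_table(pairs[label], outdir / f"pairs_{label}.tsv"))
        state["pairs"] = pairs

    elif stage == "score":
        pairs = state["pairs"]["new"]
        evidence = score_pairs(pairs, state["links"], state["s_t"],
                               cutoff=config.cutoff, min_count=config.min_assoc)
        state["evidence"] = evidence
        register("evidence", io.write_table(evidence, outdir / "evidence.tsv"))

    elif stage == "partition":
        sets = partition_validation_sets(
            state["pairs"]["old"], state["pairs"]["new"], state["links"],
            config.gwas_cut_date, config.omim_cut_date,
        )
        state["validation_sets"] = sets
        for label, df in sets.items():
            register(f"set_{label}",
                     io.write_table(df, outdir / f"set_{label}.tsv"))

    elif stage == "riskratio":
        state["riskratio"] = _riskratio_stage(config, state)
        register("riskratio",
                 io.write_table(state["riskratio"], outdir / "riskratio.tsv"))

    elif stage == "fit":
        universe = select_model_universe(state["pairs"]["new"])
        ds = state["dataset"]
        covars = ds.pairs[["gene_id", "indication", "indication_class",
                           "target_class", "dev_time_years", "rvis_percentile"]]
        universe = universe.merge(covars, on=["gene_id", "indication"], how="left")
        design = build_design(
            universe,
            categorical=["indication_class", "target_class"],
            continuous=["dev_time_years", "rvis_percentile"],
            evidence=state["evidence"],
        )
        spec = ModelSpec(degree=config.degree, chains=config.chains,
                         seed=config.seed)
        fit = fit_approval_model(universe["y"].to_numpy(), design, spec)
        w, w_se = waic(fit)
        state["fit"] = fit
        summary = fit.summary()
        summary_path = outdir / "fit_summary.tsv"
        io.write_table(summary, summary_path)
        register("fit_summary", summary_path)
        meta = {"waic": w, "waic_se": w_se,
                "converged": fit.converged,
                "standardization": {s: [b.mean, b.sd]
                                    for s, b in design.evidence.items()}}
        p = outdir / "fit_meta.json"
        p.write_text(json.dumps(meta, indent=1))
        register("fit_meta", p)

    elif stage == "curve":
        fit = state["fit"]
        curves = [odds_ratio_curve(fit, source)
                  for source in sorted(fit.design.evidence)]
        curve = pd.concat(curves, ignore_index=True)
        state["curve"] = curve
        register("curve", io.write_table(curve, outdir / "curve.tsv"))

    elif stage == "report":
        register("report", _write_report(outdir, state))


def _riskratio_stage(config: RunConfig, state) -> pd.DataFrame:
    """Risk ratios by validation set, evidence source and transition."""
    evidence = state["evidence"]
    sets = state["validation_sets"]
    rows = []
    for set_label in ("full_data", "new_genetic"):
        pairs = sets[set_label]
        links = pairs.attrs["links"]
        s_t = state["s_t"]
        scored = score_pairs(pairs, links, s_t, cutoff=config.cutoff,
                             min_count=config.min_assoc)
        for source, sub in scored.groupby("source"):
            merged = pairs.merge(
                sub[["gene_id", "indication", "e_d", "eligible"]],
                on=["gene_id", "indication"],
            )
            merged = merged.loc[merged["latest_phase"].notna()
                                & merged["eligible"].astype(bool)]
            data = pd.DataFrame({
                "phase": merged["latest_phase"].astype(int),
                "evidence": merged["e_d"].astype(int),
            })
            for from_phase, to_phase in config.transitions:
                try:
                    est = progression_risk_ratio(
                        data, to_phase=to_phase, from_phase=from_phase,
                        n_boot=config.n_boot, seed=config.seed,
                    )
                except Exception as exc:
                    logger.warning("riskratio %s/%s %d->%d undefined: %s",
                                   set_label, source, from_phase, to_phase, exc)
                    continue
                rows.append((set_label, source, from_phase, to_phase, est.rr,
                             est.ci_low, est.ci_high, len(data)))
    return pd.DataFrame(rows, columns=["set", "source", "from_phase", "to_phase",
                                       "rr", "ci_low", "ci_high", "n"])


def _write_report(outdir: Path, state) -> Path:
    lines = ["# Genetic-evidence analysis report", ""]
    rr = state.get("riskratio")
    if rr is not None and len(rr):
        lines += ["## Progression risk ratios by evidence status", "```",
                  rr.round(3).to_string(index=False), "```", ""]
    curve = state.get("curve")
    if curve is not None:
        lines += ["## Approval odds ratio vs. trait similarity", "```",
                  curve.iloc[::10].round(3).to_string(index=False), "```", ""]
    fit = state.get("fit")
    if fit is not None:
        lines += ["## Posterior summary", "```",
                  fit.summary().round(3).to_string(index=False), "```", ""]
    path = outdir / "report.md"
    path.write_text("\n".join(lines))
    return path
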