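"""End-to-end orchestration: simulate -> preprocess -> EWAS (two-stage) ->
residualize -> CLPM screen -> mediation, from one config, with a manifest.

Each stage persists its outputs as TSV/JSON under the run directory, so the
pipeline can resume from any completed stage; a rerun with the same seeds
reproduces every statistic exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .clpm import clpm_panel_screen
from .cohort import TwinCohort
from .config import RunConfig, SimulationConfig
from .ewas import EwasModelSpec, run_ewas, two_stage_replication
from .mediation import screen_mediators
from .preprocess import adjust_cell_and_batch, preprocess_cohort
from .residualize import Residualizer
from .simulate import simulate_cohort, simulate_probe_metadata

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "ewas", "clpm", "mediate")


def _replication_config(sim: SimulationConfig, offset: int) -> SimulationConfig:
    return dataclasses.replace(
        sim,
        seed=sim.seed + offset,
        replication_style=True,
        followup_fraction=0.0,
    )


def stage_simulate(cfg: RunConfig, outdir: Path):
    sim = dataclasses.replace(cfg.simulation, seed=cfg.simulation.seed + cfg.seed)
    disc, truth = simulate_cohort(sim)
    repl, _ = simulate_cohort(_replication_config(sim, cfg.replication_seed_offset))
    disc.to_dir(outdir / "discovery")
    repl.to_dir(outdir / "replication")
    (outdir / "ground_truth.json").write_text(truth.to_json())
    return disc, repl, truth


def stage_preprocess(cfg: RunConfig, outdir: Path, disc: TwinCohort, repl: TwinCohort):
    qc, _ = simulate_probe_metadata(
        disc.n_cpgs,
        disc.n_samples,
        fail_fractions={"detection": 0.01, "sex_chromosome": 0.01},
        seed=cfg.seed + 1,
    )
    qc.detection_p.columns = disc.samples.index
    qc.bead_counts.columns = disc.samples.index
    out = {}
    reports = {}
    for name, cohort, use_qc in (("discovery", disc, True), ("replication", repl, False)):
        processed, report = preprocess_cohort(
            cohort,
            qc=qc if use_qc else None,
            zygosity_cutoff=cfg.zygosity_cutoff,
            sd_threshold=cfg.sd_threshold,
        )
        processed.to_dir(outdir / f"{name}_processed")
        out[name] = processed
        reports[name] = {
            k: (v if isinstance(v, dict) else {kk: len(vv) for kk, vv in v.items()})
            for k, v in report.items()
            if k != "zygosity_counts"
        }
        if "zygosity_counts" in report:
            reports[name]["zygosity_counts"] = report["zygosity_counts"]
    (outdir / "preprocess_report.json").write_text(json.dumps(reports, indent=1))
    return out["discovery"], out["replication"], reports


def stage_ewas(cfg: RunConfig, outdir: Path, disc: TwinCohort, repl: TwinCohort):
    lambdas = {}
    disc_results, repl_results = [], []
    shared = sorted(set(disc.beta.index) & set(repl.beta.index))
    for lipid in cfg.ewas_lipids:
        spec_d = EwasModelSpec(lipid=lipid, model=cfg.ewas_model)
        res_d = run_ewas(disc, spec_d)
        spec_r = EwasModelSpec(lipid=lipid, model=cfg.ewas_model, replication=True)
        res_r = run_ewas(repl.subset(repl.samples.index), spec_r)
        res_r.table = res_r.table.loc[res_r.table.index.intersection(shared)]
        disc_results.append(res_d)
        repl_results.append(res_r)
        lambdas[lipid] = res_d.lambda_
        res_d.table.to_csv(outdir / f"ewas_{lipid}_discovery.tsv", sep="\t")
        res_r.table.to_csv(outdir / f"ewas_{lipid}_replication.tsv", sep="\t")
    replicated = two_stage_replication(disc_results, repl_results, alpha=cfg.alpha)
    replicated.to_csv(outdir / "replicated_associations.tsv", sep="\t", index=False)
    return replicated, lambdas


def stage_clpm(cfg: RunConfig, outdir: Path, disc: TwinCohort, replicated: pd.DataFrame):
    hits = replicated[replicated["replicated"]]
    cpgs = sorted(set(hits["cpg"]))
    if not cpgs:
        logger.info("no replicated associations; CLPM screen skipped")
        return pd.DataFrame(), None
    adjusted = adjust_cell_and_batch(
        disc.beta.loc[cpgs],
        disc.samples[disc.cell_columns],
        disc.samples["batch"],
    )
    resid = Residualizer().fit(disc, adjusted, cpgs=cpgs)
    resid.to_long().to_csv(outdir / "residuals_long.tsv", sep="\t", index=False)
    screen = clpm_panel_screen(
        hits[["cpg", "lipid"]], resid, strata=cfg.strata, alpha=cfg.alpha
    )
    screen.to_csv(outdir / "clpm_screen.tsv", sep="\t", index=False)
    return screen, resid


def stage_mediate(cfg: RunConfig, outdir: Path, screen: pd.DataFrame, resid):
    if screen is None or len(screen) == 0 or resid is None:
        return pd.DataFrame()
    med = screen_mediators(screen, resid, alpha=cfg.alpha)
    med.to_csv(outdir / "mediation.tsv", sep="\t", index=False)
    return med


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in order and return the run manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(cfg.to_yaml())
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "stages_completed": [],
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    disc = repl = replicated = screen = resid = None
    try:
        if "simulate" in cfg.stages:
            disc, repl, _ = stage_simulate(cfg, outdir)
            manifest["n_samples"] = {"discovery": disc.n_samples, "replication": repl.n_samples}
            manifest["n_cpgs"] = disc.n_cpgs
            manifest["stages_completed"].append("simulate")
        if "preprocess" in cfg.stages:
            if disc is None:
                disc = TwinCohort.from_dir(outdir / "discovery")
                repl = TwinCohort.from_dir(outdir / "replication")
            disc, repl, reports = stage_preprocess(cfg, outdir, disc, repl)
            manifest["preprocess"] = reports
            manifest["stages_completed"].append("preprocess")
        if "ewas" in cfg.stages:
            if disc is None:
                disc = TwinCohort.from_dir(outdir / "discovery_processed")
                repl = TwinCohort.from_dir(outdir / "replication_processed")
            replicated, lambdas = stage_ewas(cfg, outdir, disc, repl)
            manifest["lambda"] = lambdas
            manifest["n_replicated"] = int(replicated["replicated"].sum())
            manifest["stages_completed"].append("ewas")
        if "clpm" in cfg.stages:
            if replicated is None:
                replicated = pd.read_csv(outdir / "replicated_associations.tsv", sep="\t")
            if disc is None:
                disc = TwinCohort.from_dir(outdir / "discovery_processed")
            screen, resid = stage_clpm(cfg, outdir, disc, replicated)
            if len(screen):
                manifest["clpm_hits"] = int(
                    ((screen["p_adj_rho1"] < cfg.alpha) | (screen["p_adj_rho2"] < cfg.alpha)).sum()
                )
            else:
                manifest["clpm_hits"] = 0
            manifest["stages_completed"].append("clpm")
        if "mediate" in cfg.stages:
            med = stage_mediate(cfg, outdir, screen, resid)
            if len(med) and "proportion_mediated" in med.columns:
                manifest["mediation_proportions"] = {
                    f"{r['cpg']}x{r['lipid']}": r["proportion_mediated"]
                    for _, r in med.iterrows()
                    if r.get("mediation_attempted")
                }
            else:
                manifest["mediation_proportions"] = {}
            manifest["stages_completed"].append("mediate")
    except Exception as err:
        manifest["error"] = f"{type(err).__name__}: {err}"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        raise
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
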