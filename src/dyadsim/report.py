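"""End-to-end pipeline: simulate -> score -> similarity -> associate -> report.

One YAML config drives the whole run; outputs are the synthetic input files,
per-individual score CSVs, per-dyad similarity CSVs, the tidy association
results CSV, a Markdown report, and a JSON run manifest with file digests so
a run can be verified as reproduced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import panel_io, pgs, similarity as sim
from .association import (
    BatteryInputs,
    BatteryOptions,
    results_to_frame,
    run_analysis_battery,
)
from .synthetic_data import (
    SimulationConfig,
    simulate_control_genotypes,
    simulate_phenotypes,
    simulate_trios,
    write_cohort,
)

logger = logging.getLogger(__name__)

_SIM_KEYS = {f.name for f in dataclasses.fields(SimulationConfig)}
_ANALYSIS_KEYS = {
    "q", "min_n", "flip_marital_outcome", "min_callrate", "fixed_denominator",
    "genotype_format", "n_snps_control", "missing_policy",
}


def load_config(path: str | Path) -> dict:
    """Load and validate the YAML config (fails fast on unknown keys)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    unknown_top = set(raw) - {"simulation", "analysis"}
    if unknown_top:
        raise ValueError(f"unknown config sections: {sorted(unknown_top)}")
    sim_cfg = raw.get("simulation", {}) or {}
    ana_cfg = raw.get("analysis", {}) or {}
    bad = set(sim_cfg) - _SIM_KEYS
    if bad:
        raise ValueError(f"unknown simulation keys: {sorted(bad)}")
    bad = set(ana_cfg) - _ANALYSIS_KEYS
    if bad:
        raise ValueError(f"unknown analysis keys: {sorted(bad)}")
    SimulationConfig(**sim_cfg)  # validates values
    return {"simulation": sim_cfg, "analysis": ana_cfg}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name: str, start: float) -> None:
    logger.info("stage %-12s done in %.2fs", name, time.perf_counter() - start)


def run_pipeline(
    config_path: str | Path | None = None,
    outdir: str | Path = "results",
    seed: int | None = None,
    config: dict | None = None,
) -> Path:
    """Run the full synthetic analysis; returns the output directory.

    ``seed`` overrides the config's simulation seed when given. The same seed
    and config reproduce byte-identical score/similarity/results CSVs.
    """
    if config is None:
        config = load_config(config_path) if config_path else {"simulation": {}, "analysis": {}}
    sim_kwargs = dict(config.get("simulation", {}))
    if seed is not None:
        sim_kwargs["seed"] = seed
    cfg = SimulationConfig(**sim_kwargs)
    ana = dict(config.get("analysis", {}))
    q = float(ana.get("q", 0.25))
    min_n = int(ana.get("min_n", 30))
    min_callrate = float(ana.get("min_callrate", 0.8))
    fixed_denominator = bool(ana.get("fixed_denominator", False))
    genotype_format = str(ana.get("genotype_format", "tsv"))
    n_snps_control = int(ana.get("n_snps_control", 87))
    missing_policy = str(ana.get("missing_policy", "skip"))
    flip = bool(ana.get("flip_marital_outcome", True))

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "config": {"simulation": dataclasses.asdict(cfg), "analysis": ana},
        "files": {},
        "row_counts": {},
    }

    # --- simulate -----------------------------------------------------------
    t0 = time.perf_counter()
    rng = cfg.rng()
    panel, cohort = simulate_trios(cfg, rng)
    mc_dyads = cohort.dyads.loc[cohort.dyads["dyad_type"] == "mother_child"]
    mp_dyads = cohort.dyads.loc[cohort.dyads["dyad_type"] == "mother_partner"]
    sim_mc_raw = sim.cohort_similarity(cohort.mothers, cohort.children, mc_dyads,
                                       min_callrate=min_callrate,
                                       fixed_denominator=fixed_denominator)
    sim_mp_raw = sim.cohort_similarity(cohort.mothers, cohort.fathers, mp_dyads,
                                       min_callrate=min_callrate,
                                       fixed_denominator=fixed_denominator)
    sim_mc_z = sim.standardize_similarity(sim_mc_raw)["z"].to_numpy()
    sim_mp_z = sim.standardize_similarity(sim_mp_raw)["z"].to_numpy()
    phenotypes = simulate_phenotypes(cohort, sim_mc_z, cfg, rng,
                                     similarity_mp_z=sim_mp_z)
    ctrl_panel, ctrl_m, ctrl_f, ctrl_c = simulate_control_genotypes(
        cohort, cfg, rng, n_snps=n_snps_control)
    datadir = outdir / "inputs"
    paths = write_cohort(panel, cohort, phenotypes, datadir,
                         genotype_format=genotype_format)
    panel_io.write_weights(ctrl_panel, datadir / "panel_control.tsv")
    for role, gm in (("mothers", ctrl_m), ("children", ctrl_c)):
        p = datadir / f"genotypes_control_{role}.tsv"
        if genotype_format == "vcf":
            p = p.with_suffix(".vcf")
            panel_io.write_vcf(gm, ctrl_panel, p)
        else:
            panel_io.write_genotypes(gm, p)
        paths[f"control_{role}"] = p
    paths["control_panel"] = datadir / "panel_control.tsv"
    _stage("simulate", t0)

    # --- read back through the I/O layer and score --------------------------
    t0 = time.perf_counter()
    panel_r = panel_io.read_weights(paths["panel"])
    gms = {
        role: panel_io.read_genotypes(paths[role], panel_r, format=genotype_format)
        for role in ("mothers", "fathers", "children")
    }
    dyads = panel_io.read_dyads(paths["dyads"])
    pheno = panel_io.read_phenotypes(paths["phenotypes"])
    scores = {}
    for role, gm in gms.items():
        sv = pgs.standardize(pgs.compute_pgs(gm, panel_r, missing_policy=missing_policy))
        scores[role] = sv
        pgs.write_scores(sv, outdir / f"scores_{role}.csv")
    _stage("score", t0)

    # --- similarity ----------------------------------------------------------
    t0 = time.perf_counter()
    mc_dyads = dyads.loc[dyads["dyad_type"] == "mother_child"]
    mp_dyads = dyads.loc[dyads["dyad_type"] == "mother_partner"]
    sim_mc = sim.standardize_similarity(
        sim.cohort_similarity(gms["mothers"], gms["children"], mc_dyads,
                              min_callrate=min_callrate,
                              fixed_denominator=fixed_denominator))
    sim_mp = sim.standardize_similarity(
        sim.cohort_similarity(gms["mothers"], gms["fathers"], mp_dyads,
                              min_callrate=min_callrate,
                              fixed_denominator=fixed_denominator))
    ctrl_panel_r = panel_io.read_weights(paths["control_panel"])
    ctrl_gm_m = panel_io.read_genotypes(paths["control_mothers"], ctrl_panel_r,
                                        format=genotype_format)
    ctrl_gm_c = panel_io.read_genotypes(paths["control_children"], ctrl_panel_r,
                                        format=genotype_format)
    sim_neg = sim.standardize_similarity(
        sim.cohort_similarity(ctrl_gm_m, ctrl_gm_c, mc_dyads,
                              min_callrate=min_callrate,
                              fixed_denominator=fixed_denominator))
    sim_mc.to_csv(outdir / "similarity_mother_child.csv", index=False)
    sim_mp.to_csv(outdir / "similarity_mother_partner.csv", index=False)
    sim_neg.to_csv(outdir / "similarity_control.csv", index=False)
    _stage("similarity", t0)

    # --- associate ------------------------------------------------------------
    t0 = time.perf_counter()
    inputs = BatteryInputs(
        mother_scores=scores["mothers"], child_scores=scores["children"],
        partner_scores=scores["fathers"], similarity_mc=sim_mc,
        similarity_mp=sim_mp, similarity_negative=sim_neg,
        phenotypes=pheno, dyads=dyads,
    )
    opts = BatteryOptions(q=q, min_n=min_n, flip_marital_outcome=flip)
    results = run_analysis_battery(inputs, opts)
    res_df = results_to_frame(results)
    res_path = outdir / "results.csv"
    res_df.to_csv(res_path, index=False)
    _stage("associate", t0)

    # --- report + manifest ----------------------------------------------------
    report_path = outdir / "report.md"
    report_path.write_text(render_report(res_df, sim_mc, sim_mp, q))
    for label, p in {**paths,
                     "results": res_path,
                     "similarity_mc": outdir / "similarity_mother_child.csv",
                     "similarity_mp": outdir / "similarity_mother_partner.csv",
                     "similarity_control": outdir / "similarity_control.csv",
                     }.items():
        manifest["files"][label] = _sha256(Path(p))
    manifest["row_counts"] = {
        "trios": cfg.n_trios,
        "dyads": int(len(dyads)),
        "results": int(len(res_df)),
    }
    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir


def _fmt_row(r: pd.Series) -> str:
    if r.get("note") == "insufficient_n" or not np.isfinite(r["beta_std"]):
        return (f"| {r['exposure']} | {r['outcome']} | {r['stratum']} | "
                f"-- | -- | -- | {int(r['n'])} (flagged: {r['note']}) |")
    return (f"| {r['exposure']} | {r['outcome']} | {r['stratum']} | "
            f"{r['beta_std']:.3f} | ({r['ci_low']:.3f}, {r['ci_high']:.3f}) | "
            f"{r['p']:.3g} | {int(r['n'])} |")


def render_report(res_df: pd.DataFrame, sim_mc: pd.DataFrame,
                  sim_mp: pd.DataFrame, q: float) -> str:
    """Markdown report: similarity summaries, the full coefficient listing in
    both per-SD and per-unit-proportion scalings, and the quantile-strata table."""
    lines = ["# Dyadic similarity analysis report", ""]
    lines.append("## Similarity score summaries")
    lines.append("")
    lines.append("| dyad type | n | mean | min | max | SD |")
    lines.append("|---|---|---|---|---|---|")
    sd_by_exposure = {}
    for name, df in (("mother_child", sim_mc), ("mother_partner", sim_mp)):
        p = df["proportion"].dropna()
        sd_by_exposure[name] = p.std(ddof=1)
        lines.append(f"| {name} | {len(p)} | {p.mean():.4f} | {p.min():.4f} | "
                     f"{p.max():.4f} | {p.std(ddof=1):.4f} |")
    lines += ["", "## Association results (standardized betas)", ""]
    lines.append("| exposure | outcome | stratum | beta (per SD) | 95% CI | p | n |")
    lines.append("|---|---|---|---|---|---|---|")
    for _, r in res_df.iterrows():
        lines.append(_fmt_row(r))
    lines += ["", "## Joint-quantile strata (mother-child similarity on enjoyment)", ""]
    lines.append(f"| stratum (q={q:g}) | beta | 95% CI | p | n |")
    lines.append("|---|---|---|---|---|")
    strata = res_df[(res_df["exposure"] == "similarity_mc")
                    & res_df["stratum"].str.startswith(("both_high", "both_low"))]
    for _, r in strata.iterrows():
        if np.isfinite(r["beta_std"]):
            lines.append(f"| {r['stratum']} | {r['beta_std']:.3f} | "
                         f"({r['ci_low']:.3f}, {r['ci_high']:.3f}) | "
                         f"{r['p']:.3g} | {int(r['n'])} |")
        else:
            lines.append(f"| {r['stratum']} | -- | -- | -- | {int(r['n'])} |")
    lines += ["", "## Per-unit-proportion scaling", "",
              "Betas above are outcome-SD per similarity-SD; dividing by the raw",
              "proportion SD gives outcome-SD per unit proportion:", ""]
    lines.append("| exposure | raw proportion SD | example: overall enjoyment beta per unit |")
    lines.append("|---|---|---|")
    for name, key in (("similarity_mc", "mother_child"),
                      ("similarity_mp", "mother_partner")):
        sd = sd_by_exposure[key]
        row = res_df[(res_df["exposure"] == name) & (res_df["outcome"] == "enjoyment")
                     & (res_df["stratum"] == "overall")]
        if len(row) and np.isfinite(row.iloc[0]["beta_std"]) and sd > 0:
            per_unit = row.iloc[0]["beta_std"] / sd
            lines.append(f"| {name} | {sd:.4f} | {per_unit:.3f} |")
    lines.append("")
    return "\n".join(lines)
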