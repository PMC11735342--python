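"""End-to-end orchestration: fit -> simulate -> risk -> sensitivity -> report.

One seeded run produces six CSV artifacts plus a JSON manifest:

* ``residue_summary.csv``      — detection frequencies and detected-value
  summaries per (food x analyte);
* ``posterior_parameters.csv`` — fitted (p0, mu, sigma) posterior means and
  SDs plus the mixture-mean concentration, per cell and model branch;
* ``edi_p975.csv``             — mean and P97.5 daily intake per
  (age group x food), plus all-cereal totals;
* ``hazard_index.csv``         — per-analyte HQ and summed HI (mean, P97.5)
  per age group;
* ``cancer_risk.csv``          — lifetime cancer risk table for the
  carcinogenic analyte (BP), one column per age group;
* ``sensitivity.csv``          — contribution-to-variance of every input
  (per-cell concentrations, per-food ingestion rates, body weight) to the
  hazard index, for the configured age groups.

Both concentration branches run when ``model: both``: "mcmc" draws
concentrations from the Bayesian posterior predictive (C1), "mc" from the
directly fitted lognormal (C2).

All randomness descends from the single config seed through named
``SeedSequence`` spawns keyed by sorted (analyte, food, age group) labels,
so identical configs give byte-identical outputs regardless of dict order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .censored import CensoredCount, McmcSettings, fit_mcmc, posterior_mean_concentration
from .config import PipelineConfig, config_to_raw, validate_config
from .errors import BpdRiskError, InsufficientDataError, ValidationError
from .exposure import (
    AGE_GROUPS,
    EdiDraws,
    _draw_bw,
    _draw_concentration,
    _draw_lognormal,
    fit_c2_distribution,
    percentile,
    total_edi,
)
from .residues import read_residue_table, summary_table, write_residue_table
from .risk import NG_PER_MG, RiskConstants, hazard_index, hazard_quotient, ltcr_table
from .sensitivity import contribution_to_variance
from .synthetic import generate_residues

__all__ = ["run_pipeline", "PipelineResult"]

P_HIGH = 0.975


def _seed_for(root: int, *key: str) -> np.random.SeedSequence:
    """Deterministic named substream: stable under config re-ordering."""
    digest = [hash_label(k) for k in key]
    return np.random.SeedSequence(entropy=root, spawn_key=tuple(digest))


def hash_label(label: str) -> int:
    """Stable small integer from a label (Python's hash is salted per run)."""
    h = 0
    for ch in label:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


@dataclass
class PipelineResult:
    """Outputs of one pipeline run, both in memory and on disk."""

    out_dir: Path
    summary: pd.DataFrame
    posterior: pd.DataFrame
    edi: pd.DataFrame
    hazard: pd.DataFrame
    cancer: pd.DataFrame
    sensitivity: pd.DataFrame
    manifest: dict


def _fit_cells(dataset, cfg: PipelineConfig, branches: list[str]) -> tuple[dict, pd.DataFrame]:
    """Fit every (food x analyte) cell for each requested branch."""
    sources: dict[tuple[str, str, str], object] = {}
    rows = []
    for food in dataset.food_categories:
        for analyte in cfg.analytes:
            try:
                counts = CensoredCount.from_dataset(dataset, analyte, food)
            except InsufficientDataError:
                continue
            if "mcmc" in branches:
                settings = McmcSettings(
                    n_iterations=cfg.mcmc.n_iterations,
                    n_burn_in=cfg.mcmc.n_burn_in,
                    n_chains=cfg.mcmc.n_chains,
                    seed=int(_seed_for(cfg.seed, "fit", analyte, food).generate_state(1)[0] % 2**31),
                )
                draws = fit_mcmc(counts, cfg.priors, settings)
                dist = posterior_mean_concentration(draws)
                sources[("mcmc", analyte, food)] = draws
                rows.append(
                    {
                        "model": "mcmc",
                        "food_category": food,
                        "analyte": analyte,
                        "n": counts.n_total,
                        "p0_pct_mean": dist.p0_percent[0],
                        "p0_pct_sd": dist.p0_percent[1],
                        "mu_mean": dist.mu_mean,
                        "mu_sd": dist.mu_sd,
                        "sigma_mean": dist.sigma_mean,
                        "sigma_sd": dist.sigma_sd,
                        "conc_mean_ng_g": dist.mean_c1,
                        "conc_sd_ng_g": dist.sd_c1,
                        "conc_plug_in_ng_g": dist.plug_in,
                    }
                )
            if "mc" in branches:
                if counts.n_detected < 2:
                    continue
                fit = fit_c2_distribution(counts, method="censored-mle")
                sources[("mc", analyte, food)] = fit
                rows.append(
                    {
                        "model": "mc",
                        "food_category": food,
                        "analyte": analyte,
                        "n": counts.n_total,
                        "p0_pct_mean": np.nan,
                        "p0_pct_sd": np.nan,
                        "mu_mean": fit.mu,
                        "mu_sd": np.nan,
                        "sigma_mean": fit.sigma,
                        "sigma_sd": np.nan,
                        "conc_mean_ng_g": float(np.exp(fit.mu + fit.sigma**2 / 2)),
                        "conc_sd_ng_g": np.nan,
                        "conc_plug_in_ng_g": float(np.exp(fit.mu + fit.sigma**2 / 2)),
                    }
                )
    return sources, pd.DataFrame(rows)


def _simulate_group(cfg: PipelineConfig, branch: str, group: str, sources: dict, foods: list[str]):
    """Joint Monte-Carlo draw for one (branch, age group).

    Body weight is drawn once per iteration (shared by all foods) and each
    food's ingestion rate once per iteration (shared by its analytes), so
    the input streams are aligned with the output for sensitivity.
    """
    profile = cfg.consumption[group]
    n = cfg.mc_iterations
    rng_bw = np.random.default_rng(_seed_for(cfg.seed, "sim", branch, group, "bw"))
    bw = _draw_bw(rng_bw, *profile.bw, n)
    inputs: dict[str, np.ndarray] = {"BW": bw}
    edi_cells: dict[tuple[str, str], EdiDraws] = {}
    for food in foods:
        if food not in profile.ir:
            raise ValidationError(f"consumption profile {group!r} lacks an ingestion rate for {food!r}")
        rng_ir = np.random.default_rng(_seed_for(cfg.seed, "sim", branch, group, "ir", food))
        ir = _draw_lognormal(rng_ir, *profile.ir[food], n)
        inputs[f"IR[{food}]"] = ir
        for analyte in cfg.analytes:
            src = sources.get((branch, analyte, food))
            if src is None:
                continue
            rng_c = np.random.default_rng(_seed_for(cfg.seed, "sim", branch, group, "conc", food, analyte))
            c = _draw_concentration(src, rng_c, n)
            inputs[f"C[{analyte}|{food}]"] = c
            edi_cells[(analyte, food)] = EdiDraws(
                age_group=group, analyte=analyte, food_category=food, values=c * ir / bw
            )
    return inputs, edi_cells


def run_pipeline(cfg: PipelineConfig, out_dir, *, seed: int | None = None) -> PipelineResult:
    """Run the full assessment and write all artifacts under ``out_dir``.

    ``seed`` overrides the config seed.  Raises :class:`BpdRiskError`
    subclasses on invalid configs; partial outputs already written are
    left in place for inspection.
    """
    if seed is not None:
        cfg.seed = int(seed)
        cfg.mcmc = McmcSettings(cfg.mcmc.n_iterations, cfg.mcmc.n_burn_in, cfg.mcmc.n_chains, seed=cfg.seed)
    issues = validate_config(cfg)
    if issues:
        raise ValidationError("invalid config:\n  - " + "\n  - ".join(issues))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage 1: residue data
    if cfg.residue_csv is not None:
        dataset = read_residue_table(cfg.residue_csv)
    else:
        scenario = cfg.scenario
        dataset = generate_residues(scenario, seed=int(_seed_for(cfg.seed, "residues").generate_state(1)[0] % 2**31))
        write_residue_table(dataset, out / "residues_synthetic.csv")
    summary = summary_table(dataset)
    summary.to_csv(out / "residue_summary.csv", index=False)

    # --- stage 2: concentration models
    branches = ["mcmc", "mc"] if cfg.model == "both" else [cfg.model]
    sources, posterior = _fit_cells(dataset, cfg, branches)
    posterior.to_csv(out / "posterior_parameters.csv", index=False)

    foods = dataset.food_categories
    groups = [g for g in AGE_GROUPS if g in cfg.consumption]

    # --- stage 3 & 4: exposure simulation and risk characterization
    edi_rows, hi_rows, sens_rows = [], [], []
    cancer_frames = []
    for branch in branches:
        edi_mean_mg: dict[str, float] = {}
        edi_p975_mg: dict[str, float] = {}
        for group in groups:
            inputs, cells = _simulate_group(cfg, branch, group, sources, foods)
            if not cells:
                continue
            # per-food totals over analytes, and the all-cereal total
            for food in foods:
                parts = [d for (a, f), d in cells.items() if f == food]
                if not parts:
                    continue
                tot = total_edi(parts)
                edi_rows.append(
                    {
                        "model": branch,
                        "age_group": group,
                        "food_category": food,
                        "edi_mean_ng_kg_day": tot.mean(),
                        "edi_p975_ng_kg_day": percentile(tot, P_HIGH),
                    }
                )
            grand = total_edi(list(cells.values()))
            edi_rows.append(
                {
                    "model": branch,
                    "age_group": group,
                    "food_category": "all",
                    "edi_mean_ng_kg_day": grand.mean(),
                    "edi_p975_ng_kg_day": percentile(grand, P_HIGH),
                }
            )

            # HQ per analyte (summed over foods), HI across analytes
            hq_draws: dict[str, np.ndarray] = {}
            for analyte in cfg.constants.hi_components:
                parts = [d for (a, f), d in cells.items() if a == analyte]
                if not parts:
                    continue
                tot_a = total_edi(parts)
                hq_draws[analyte] = hazard_quotient(tot_a, cfg.constants.rfd[analyte])
            if hq_draws:
                hi = hazard_index(list(hq_draws.values()))
                row = {
                    "model": branch,
                    "age_group": group,
                    "hi_mean": float(hi.mean()),
                    "hi_p975": percentile(hi, P_HIGH),
                }
                for a, hq in hq_draws.items():
                    row[f"hq_mean[{a}]"] = float(hq.mean())
                    row[f"hq_p975[{a}]"] = percentile(hq, P_HIGH)
                hi_rows.append(row)

                if group in cfg.sensitivity_groups:
                    res = contribution_to_variance(inputs, hi, method=cfg.sensitivity_method)
                    for name in res.ranking:
                        sens_rows.append(
                            {
                                "model": branch,
                                "age_group": group,
                                "input": name,
                                "contribution_percent": res.contributions[name],
                            }
                        )

            # carcinogenic branch: BP intake totals in mg/kg/day
            bp_parts = [d for (a, f), d in cells.items() if a == "BP"]
            if bp_parts:
                bp_tot = total_edi(bp_parts)
                edi_mean_mg[group] = bp_tot.mean() / NG_PER_MG
                edi_p975_mg[group] = percentile(bp_tot, P_HIGH) / NG_PER_MG
        if edi_mean_mg:
            tbl = ltcr_table(edi_mean_mg, edi_p975_mg, cfg.constants)
            tbl.insert(0, "model", branch)
            cancer_frames.append(tbl)

    edi = pd.DataFrame(edi_rows)
    hazard = pd.DataFrame(hi_rows)
    cancer = pd.concat(cancer_frames, ignore_index=True) if cancer_frames else pd.DataFrame()
    sens = pd.DataFrame(sens_rows)
    edi.to_csv(out / "edi_p975.csv", index=False)
    hazard.to_csv(out / "hazard_index.csv", index=False)
    cancer.to_csv(out / "cancer_risk.csv", index=False)
    sens.to_csv(out / "sensitivity.csv", index=False)

    manifest = {
        "package": "bpdrisk",
        "version": __version__,
        "seed": cfg.seed,
        "config": config_to_raw(cfg),
        "artifacts": [
            "residue_summary.csv",
            "posterior_parameters.csv",
            "edi_p975.csv",
            "hazard_index.csv",
            "cancer_risk.csv",
            "sensitivity.csv",
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return PipelineResult(
        out_dir=out,
        summary=summary,
        posterior=posterior,
        edi=edi,
        hazard=hazard,
        cancer=cancer,
        sensitivity=sens,
        manifest=manifest,
    )
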