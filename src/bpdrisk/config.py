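"""YAML/JSON configuration for the full pipeline.

A single config file drives residue input (CSV path or synthetic
scenario), priors, MCMC settings, Monte-Carlo settings, consumption
profiles, risk constants and the sensitivity request.  ``validate_config``
collects *all* violations rather than stopping at the first, so a config
can be repaired in one pass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .censored import McmcSettings, PriorSpec
from .errors import SchemaError, ValidationError
from .exposure import AGE_GROUPS, ConsumptionProfile
from .risk import RiskConstants
from .synthetic import ResidueScenario, ScenarioSpec, default_consumption, table2_preset

__all__ = ["PipelineConfig", "load_config", "save_config", "validate_config"]


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    The pipeline's consumption profiles come from ``consumption`` (a
    scenario's own profiles only drive the synthetic module; set both when
    overriding them for a synthetic run).
    """

    seed: int = 0
    model: str = "both"  # mcmc | mc | both
    residue_csv: str | None = None
    scenario: ScenarioSpec | None = None
    priors: PriorSpec = field(default_factory=PriorSpec)
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    mc_iterations: int = 10_000
    consumption: dict[str, ConsumptionProfile] = field(default_factory=default_consumption)
    constants: RiskConstants = field(default_factory=RiskConstants)
    sensitivity_groups: list[str] = field(default_factory=lambda: ["0-3"])
    sensitivity_method: str = "spearman"
    analytes: list[str] = field(default_factory=lambda: ["BP", "4-MBP", "BP-3"])


def _profiles_to_raw(profiles: dict[str, ConsumptionProfile]) -> dict:
    return {
        g: {"bw": list(p.bw), "ir": {f: list(v) for f, v in p.ir.items()}}
        for g, p in profiles.items()
    }


def _profiles_from_raw(raw: dict) -> dict[str, ConsumptionProfile]:
    return {
        g: ConsumptionProfile(
            age_group=g,
            ir={f: tuple(float(x) for x in v) for f, v in d["ir"].items()},
            bw=tuple(float(x) for x in d["bw"]),
        )
        for g, d in raw.items()
    }


def _scenario_to_raw(s: ScenarioSpec) -> dict:
    return {
        "seed": s.seed,
        "residues": [
            {
                "analyte": c.analyte,
                "food_category": c.food_category,
                "p0": c.p0,
                "mu": c.mu,
                "sigma": c.sigma,
                "lod": c.lod,
                "n_samples": c.n_samples,
                "lod_jitter": c.lod_jitter,
            }
            for c in s.residues
        ],
        "consumption": _profiles_to_raw(s.consumption),
    }


def _scenario_from_raw(raw: dict) -> ScenarioSpec:
    if raw == "default" or raw is True:
        from .synthetic import default_scenario

        return default_scenario()
    cells = [
        ResidueScenario(
            analyte=c["analyte"],
            food_category=c["food_category"],
            p0=float(c["p0"]),
            mu=float(c["mu"]),
            sigma=float(c["sigma"]),
            lod=float(c["lod"]),
            n_samples=int(c["n_samples"]),
            lod_jitter=float(c.get("lod_jitter", 0.0)),
        )
        for c in raw.get("residues", [])
    ]
    consumption = _profiles_from_raw(raw["consumption"]) if "consumption" in raw else default_consumption()
    return ScenarioSpec(residues=cells, consumption=consumption, seed=int(raw.get("seed", 0)))


def config_to_raw(cfg: PipelineConfig) -> dict:
    raw: dict = {
        "seed": cfg.seed,
        "model": cfg.model,
        "analytes": list(cfg.analytes),
        "priors": {
            "p0_beta": list(cfg.priors.p0_beta),
            "mu_normal": list(cfg.priors.mu_normal),
            "sigma2_inv_gamma": list(cfg.priors.sigma2_inv_gamma),
            "mu_parameterization": cfg.priors.mu_parameterization,
        },
        "mcmc": {
            "n_iterations": cfg.mcmc.n_iterations,
            "n_burn_in": cfg.mcmc.n_burn_in,
            "n_chains": cfg.mcmc.n_chains,
        },
        "simulation": {"n_iterations": cfg.mc_iterations},
        "consumption": _profiles_to_raw(cfg.consumption),
        "risk_constants": {
            "rfd": dict(cfg.constants.rfd),
            "csf": cfg.constants.csf,
            "ef": cfg.constants.ef,
            "at_days": cfg.constants.at_days,
            "ed_years": dict(cfg.constants.ed_years),
            "hi_components": list(cfg.constants.hi_components),
        },
        "sensitivity": {"age_groups": list(cfg.sensitivity_groups), "method": cfg.sensitivity_method},
    }
    if cfg.residue_csv is not None:
        raw["residues"] = {"csv": cfg.residue_csv}
    elif cfg.scenario is not None:
        raw["residues"] = {"synthetic": _scenario_to_raw(cfg.scenario)}
    return raw


def config_from_raw(raw: dict) -> PipelineConfig:
    cfg = PipelineConfig()
    cfg.seed = int(raw.get("seed", 0))
    cfg.model = str(raw.get("model", "both"))
    cfg.analytes = list(raw.get("analytes", cfg.analytes))
    if "priors" in raw:
        p = raw["priors"]
        cfg.priors = PriorSpec(
            p0_beta=tuple(p.get("p0_beta", (1.0, 1.0))),
            mu_normal=tuple(p.get("mu_normal", (0.0, 0.01))),
            sigma2_inv_gamma=tuple(p.get("sigma2_inv_gamma", (0.1, 0.1))),
            mu_parameterization=p.get("mu_parameterization", "precision"),
        )
    if "mcmc" in raw:
        m = raw["mcmc"]
        cfg.mcmc = McmcSettings(
            n_iterations=int(m.get("n_iterations", 14_000)),
            n_burn_in=int(m.get("n_burn_in", 4_000)),
            n_chains=int(m.get("n_chains", 1)),
            seed=cfg.seed,
        )
    if "simulation" in raw:
        cfg.mc_iterations = int(raw["simulation"].get("n_iterations", 10_000))
    if "consumption" in raw and raw["consumption"] != "default":
        cfg.consumption = _profiles_from_raw(raw["consumption"])
    if "risk_constants" in raw:
        rc = raw["risk_constants"]
        cfg.constants = RiskConstants(
            rfd={k: float(v) for k, v in rc.get("rfd", RiskConstants().rfd).items()},
            csf=float(rc.get("csf", 4.8e-3)),
            ef=float(rc.get("ef", 365.0)),
            at_days=float(rc.get("at_days", 25_550.0)),
            ed_years={k: float(v) for k, v in rc.get("ed_years", RiskConstants().ed_years).items()},
            hi_components=tuple(rc.get("hi_components", ("BP", "4-MBP", "BP-3"))),
        )
    if "sensitivity" in raw:
        cfg.sensitivity_groups = list(raw["sensitivity"].get("age_groups", ["0-3"]))
        cfg.sensitivity_method = raw["sensitivity"].get("method", "spearman")
    residues = raw.get("residues", {"synthetic": "default"})
    if "csv" in residues:
        cfg.residue_csv = residues["csv"]
    else:
        cfg.scenario = _scenario_from_raw(residues.get("synthetic", "default"))
    return cfg


def load_config(path) -> PipelineConfig:
    """Load a YAML (or JSON — valid YAML) pipeline config."""
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise SchemaError(f"{path}: cannot parse config: {exc}") from exc
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: config must be a mapping, got {type(raw).__name__}")
    try:
        return config_from_raw(raw)
    except (KeyError, TypeError, ValueError, ValidationError) as exc:
        raise SchemaError(f"{path}: invalid config: {exc}") from exc


def save_config(cfg: PipelineConfig, path) -> None:
    path = Path(path)
    raw = config_to_raw(cfg)
    if path.suffix == ".json":
        path.write_text(json.dumps(raw, indent=2))
    else:
        path.write_text(yaml.safe_dump(raw, sort_keys=False))


def validate_config(cfg: PipelineConfig) -> list[str]:
    """Return every violation found (empty list = valid)."""
    issues: list[str] = []
    if cfg.model not in ("mcmc", "mc", "both"):
        issues.append(f"model must be 'mcmc', 'mc' or 'both', got {cfg.model!r}")
    if cfg.residue_csv is None and cfg.scenario is None:
        issues.append("residues: either a csv path or a synthetic scenario is required")
    if cfg.residue_csv is not None and not Path(cfg.residue_csv).exists():
        issues.append(f"residues.csv: file not found: {cfg.residue_csv}")
    if cfg.mc_iterations < 1:
        issues.append("simulation.n_iterations must be >= 1")
    missing = [g for g in AGE_GROUPS if g not in cfg.consumption]
    if missing:
        issues.append(f"consumption: missing age group(s) {missing}; expected all of {list(AGE_GROUPS)}")
    for g, p in cfg.consumption.items():
        if p.bw[0] <= 0:
            issues.append(f"consumption[{g}].bw mean must be positive")
    for a, v in cfg.constants.rfd.items():
        if v <= 0:
            issues.append(f"risk_constants.rfd[{a}] must be positive")
    if cfg.constants.csf <= 0:
        issues.append("risk_constants.csf must be positive")
    for g in cfg.sensitivity_groups:
        if g not in AGE_GROUPS:
            issues.append(f"sensitivity.age_groups: unknown group {g!r}; expected one of {list(AGE_GROUPS)}")
    for a in cfg.constants.hi_components:
        if a not in cfg.constants.rfd:
            issues.append(f"risk_constants.hi_components: {a!r} has no RfD entry")
    return issues
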