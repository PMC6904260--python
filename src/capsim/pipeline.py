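"""End-to-end orchestration: synth -> baseline -> scenarios -> impact.

A :class:`RunConfig` names either the four input CSVs or a synthetic-data
configuration; :func:`run_pipeline` executes every stage, writes
``baseline.csv``, ``scenarios.csv``, ``impact.csv``, ``summary.csv``,
``models.json`` and ``run_log.json`` into the output directory, and is
byte-reproducible for a fixed config and seed.
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

from . import baseline as bl
from . import capacity as cap
from . import scenarios as sc
from .core_data import (
    COST_CATEGORIES,
    PAYERS,
    PolicyTables,
    PopulationTable,
    StatePanel,
    exclude_qhp_states,
    load_policy,
    read_panel,
    write_table,
)
from .synthetic import SyntheticConfig, generate_all

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One reproducible run.

    Either ``synth`` carries keyword overrides for :class:`SyntheticConfig`
    (empty dict = defaults), or the four ``*_path`` fields name input CSVs.
    """

    out_dir: str = "capsim_out"
    seed: int = 0
    synth: dict | None = field(default_factory=dict)
    panel_path: str | None = None
    population_path: str | None = None
    policy_path: str | None = None
    cpi_path: str | None = None
    scenario_years: tuple[int, int] = (2020, 2024)
    scenarios: tuple[str, ...] = ("S1", "S2", "S3")
    inflation: str = "fixed"          # "fixed" (2.3%/yr) or "cpim" (estimated path)
    deviance_mode: str = "annual"
    floor_at_zero: bool = True
    smooth_seed: bool = False
    enrollment_assumptions: tuple[str, ...] = ("no_cuts", "proportional_cuts")
    sweep_levels: tuple[float, ...] = cap.DEFAULT_SWEEP_LEVELS

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown run-config key(s): {sorted(unknown)}")
        for key in ("scenario_years", "scenarios", "enrollment_assumptions", "sweep_levels"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the analytic configuration (output location excluded)."""
        fields = dataclasses.asdict(self)
        fields.pop("out_dir")
        blob = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    """Wraps a failure with the name of the pipeline stage it occurred in."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise StageError(f"stage '{name}': {exc}") from exc
        return wrapped
    return deco


@_stage("load_inputs")
def load_inputs(config: RunConfig):
    if config.synth is not None:
        synth_cfg = SyntheticConfig(**{"seed": config.seed, **config.synth})
        panel, population, policy, truth = generate_all(synth_cfg)
        return panel, population, policy, truth
    for name in ("panel_path", "population_path", "policy_path", "cpi_path"):
        path = getattr(config, name)
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"run config {name} missing or not found: {path}")
    panel = read_panel(config.panel_path, "panel")
    population = read_panel(config.population_path, "population")
    policy = load_policy(config.policy_path, config.cpi_path)
    return panel, population, policy, None


@_stage("fit_models")
def fit_models(panel: StatePanel, population: PopulationTable, policy: PolicyTables):
    patient_models = {p: bl.fit_patient_model(panel, population, p) for p in PAYERS}
    revenue_models = {p: bl.fit_revenue_model(panel, policy, p) for p in PAYERS}
    fte_models = {c: bl.fit_fte_cost_model(panel, c) for c in COST_CATEGORIES}
    return patient_models, revenue_models, fte_models


@_stage("scenarios")
def run_scenarios(
    panel: StatePanel,
    population: PopulationTable,
    policy: PolicyTables,
    patient_models: dict,
    projection: bl.BaselineProjection,
    config: RunConfig,
) -> pd.DataFrame:
    y0, y1 = config.scenario_years
    scenario_years = list(range(y0, y1 + 1))

    split_proj = sc.enrollment_split(
        patient_models["medicaid"], population, policy,
        list(range(y0 - 1, y1 + 1)))
    shares = sc.build_federal_shares(
        bl.BaselineProjection(
            projection.df[projection.df["year"].isin(scenario_years)],
            projection.base_year),
        split_proj, policy)

    split_hist = sc.enrollment_split(
        patient_models["medicaid"], population, policy, [2015, 2016])
    hist_shares = sc.historical_federal_shares(panel, split_hist, policy)
    trad = hist_shares.group("traditional").set_index(["state", "year"])
    base_trad_federal = trad.xs(2016, level="year")["federal"]
    pc_fed = trad["federal"] / trad["enrollees"]
    base_pc_federal = pc_fed.groupby("state").mean()

    if config.inflation == "fixed":
        path = sc.fixed_inflation_path(range(2016, y1 + 1),
                                       rate=policy.block_grant_inflation)
    elif config.inflation == "cpim":
        path = sc.estimate_cpim_path(policy.cpi, base_year=2016, through=y1)
    else:
        raise ValueError(f"unknown inflation mode {config.inflation!r}")

    pc_expend = sc.projected_pc_expenditure(projection, split_proj)

    pieces = [sc.scenario_s0(shares)]
    if "S1" in config.scenarios:
        pieces.append(sc.scenario_s1_efmap_phaseout(
            shares, policy, floor_at_zero=config.floor_at_zero))
    if "S2" in config.scenarios:
        pieces.append(sc.scenario_s2_block_grant(
            shares, base_trad_federal, path, floor_at_zero=config.floor_at_zero))
    if "S3" in config.scenarios:
        pieces.append(sc.scenario_s3_per_capita_cap(
            shares, base_pc_federal, path, pc_expend, start_year=y0,
            deviance_mode=config.deviance_mode, floor_at_zero=config.floor_at_zero))
    results = pd.concat(pieces, ignore_index=True)
    return sc.compute_shortfall(projection, results)


@_stage("impact")
def run_impact(results: pd.DataFrame, projection: bl.BaselineProjection,
               config: RunConfig) -> pd.DataFrame:
    frames = [
        cap.compute_fte_impact(results, projection, enrollment_assumption=a)
        for a in config.enrollment_assumptions
    ]
    frames.append(cap.sensitivity_sweep(results, projection, config.sweep_levels))
    return pd.concat(frames, ignore_index=True)


def summarize_by_expansion_status(
    results: pd.DataFrame,
    impacts: pd.DataFrame,
    policy: PolicyTables,
    weight: str = "enrollees",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean shortfall percentages and FTE cuts by expansion status.

    Aggregates across states within {expansion, nonexpansion} x scenario x
    group, weighting by projected enrollees by default (``weight='none'``
    gives unweighted means), and appends most/least-affected state rankings
    by final-year all-group shortfall percentage.
    """
    expansion_flag = {
        s: policy.is_expansion(s) for s in results["state"].unique()
    }
    res = results.copy()
    res["expansion_status"] = res["state"].map(
        lambda s: "expansion" if expansion_flag[s] else "nonexpansion")

    rows = []
    for (status, scenario, group), grp in res.groupby(
            ["expansion_status", "scenario", "group"]):
        valid = grp[~grp["pct_undefined"] & grp["shortfall_pct"].notna()]
        if valid.empty:
            continue
        if weight == "enrollees" and valid["enrollees"].sum() > 0:
            mean_pct = float(np.average(valid["shortfall_pct"],
                                        weights=valid["enrollees"]))
        else:
            mean_pct = float(valid["shortfall_pct"].mean())
        rows.append({
            "expansion_status": status,
            "scenario": scenario,
            "group": group,
            "mean_shortfall_pct": mean_pct,
            "total_shortfall_abs": float(grp["shortfall_abs"].sum()),
            "n_states": grp["state"].nunique(),
        })
    summary = pd.DataFrame(rows)

    final_year = int(res["year"].max())
    ranking = (
        res[(res["group"] == "all") & (res["year"] == final_year)
            & (res["scenario"] != "S0")]
        .groupby("state", as_index=False)["shortfall_pct"].mean()
        .sort_values("shortfall_pct", ascending=False)
        .reset_index(drop=True)
    )
    ranking["rank_most_affected"] = np.arange(1, len(ranking) + 1)

    upper = impacts[impacts["enrollment_assumption"] == "no_cuts"]
    if not upper.empty:
        cuts = upper.groupby("state", as_index=False)["nonclinical_cut_pct"].mean()
        ranking = ranking.merge(cuts, on="state", how="left")
    return summary, ranking


def compute_all(config: RunConfig) -> dict:
    """Run every stage in memory; returns a dict of all intermediate artifacts."""
    panel, population, policy, truth = load_inputs(config)
    panel = exclude_qhp_states(panel, policy)
    patient_models, revenue_models, fte_models = fit_models(panel, population, policy)

    _, y1 = config.scenario_years
    projection = bl.project_baseline(
        panel, population, policy, patient_models, revenue_models, fte_models,
        years=list(range(max(panel.years) + 1, y1 + 1)),
        smooth_seed=config.smooth_seed)

    results = run_scenarios(panel, population, policy, patient_models,
                            projection, config)
    impacts = run_impact(results, projection, config)
    summary, ranking = summarize_by_expansion_status(results, impacts, policy)
    return {
        "panel": panel, "population": population, "policy": policy, "truth": truth,
        "patient_models": patient_models, "revenue_models": revenue_models,
        "fte_models": fte_models, "projection": projection, "results": results,
        "impacts": impacts, "summary": summary, "ranking": ranking,
    }


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and write artifacts to ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    art = compute_all(config)

    write_table(art["projection"].df, out / "baseline.csv")
    write_table(art["results"], out / "scenarios.csv")
    write_table(art["impacts"], out / "impact.csv")
    write_table(art["summary"], out / "summary.csv")
    write_table(art["ranking"], out / "ranking.csv")
    if art["truth"] is not None:
        write_table(art["panel"], out / "panel.csv")
        write_table(art["population"], out / "population.csv")
        write_table(art["policy"].policy, out / "policy_fmap.csv")
        write_table(art["policy"].cpi, out / "cpi.csv")
    _write_models_json(out / "models.json", art["patient_models"],
                       art["revenue_models"], art["fte_models"])
    with open(out / "run_log.json", "w") as fh:
        json.dump({"seed": config.seed, "config_hash": config.config_hash(),
                   "states": art["panel"].states,
                   "scenario_years": list(config.scenario_years)}, fh, indent=2)
    logger.info("pipeline complete; artifacts in %s", out)
    return out


def _write_models_json(path: Path, patient_models, revenue_models, fte_models) -> None:
    blob = {
        "patients": {
            payer: {state: m.coeffs.round(10).to_dict() for state, m in models.items()}
            for payer, models in patient_models.items()
        },
        "revenue_pc": {
            payer: {state: m.coeffs.round(10).to_dict() for state, m in models.items()}
            for payer, models in revenue_models.items()
        },
        "fte_cost": {
            cat: {state: {"beta0": m.beta0,
                          **m.betas.round(6).to_dict(),
                          "labor_growth": round(m.labor_growth, 8)}
                  for state, m in models.items()}
            for cat, models in fte_models.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(blob, fh, indent=2, sort_keys=True)
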