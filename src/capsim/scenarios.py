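"""Federal-contribution scenarios: EFMAP phase-out, block grant, per-capita cap.

The engine disaggregates projected baseline (S0) Medicaid revenues into
federal and state shares using FMAP/EFMAP match rates, then recomputes the
federal contribution under each reform:

* **S1** phases out the enhanced match for the expansion population: the
  federal contribution falls by (EFMAP - FMAP, at their base-year values)
  times the projected expansion enrollees times per-capita expenditure.
* **S2** replaces the open-ended federal match for the traditional
  population with a block grant: the base-year traditional federal
  contribution grown by a fixed 2.3%/yr (or an estimated CPI-M path),
  independent of enrollment; the expansion population is excluded from the
  grant base (its match is phased out as in S1).
* **S3** caps the federal contribution per enrollee: the base per-capita
  contribution (2015-16 traditional mean) grows by the inflation factor and
  by each state's percent deviance from the national-average projected
  per-capita expenditure, composed dynamically year over year; the federal
  contribution is the cap times total projected enrollment.

State contributions are held at base-year behavior throughout; grants and
non-Medicaid payer revenues pass through unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .baseline import BaselineProjection, counterfactual_population, project_patients
from .core_data import PolicyTables, PopulationTable, StatePanel

logger = logging.getLogger(__name__)

GROUPS = ["traditional", "expansion"]

SCENARIO_YEARS = list(range(2020, 2025))


def split_federal_state(revenue: float, fmap: float) -> tuple[float, float]:
    """Split Medicaid revenue into (federal, state) shares at a match rate."""
    if not 0.0 < fmap < 1.0:
        raise ValueError(f"fmap {fmap} outside (0, 1)")
    if revenue < 0:
        raise ValueError("revenue must be >= 0")
    federal = fmap * revenue
    return federal, revenue - federal


def fmap_match_ratio(fmap: float) -> float:
    """Federal dollars per state dollar: FMAP / (1 - FMAP)."""
    if not 0.0 < fmap < 1.0:
        raise ValueError(f"fmap {fmap} outside (0, 1)")
    return fmap / (1.0 - fmap)


# --------------------------------------------------------------------------
# inflation paths
# --------------------------------------------------------------------------

@dataclass
class InflationPath:
    """Cumulative inflation multipliers from a base year."""

    multipliers: pd.Series       # year -> multiplier; multiplier[base_year] = 1
    base_year: int
    source: str                  # "fixed_2.3pct" or "cpim_estimated"

    def multiplier(self, year: int) -> float:
        if year not in self.multipliers.index:
            raise KeyError(f"inflation path does not cover year {year}")
        return float(self.multipliers.loc[year])

    def annual_rate(self, year: int) -> float:
        """Growth from year-1 to year implied by the cumulative path."""
        return self.multiplier(year) / self.multiplier(year - 1) - 1.0


def fixed_inflation_path(years, rate: float = 0.023, base_year: int = 2016) -> InflationPath:
    all_years = sorted(set(list(years) + [base_year]))
    mult = pd.Series({y: (1.0 + rate) ** (y - base_year) for y in all_years})
    mult.index.name = "year"
    return InflationPath(mult, base_year, source=f"fixed_{rate * 100:g}pct")


def estimate_cpim_path(
    cpi: pd.DataFrame,
    base_year: int = 2016,
    through: int = 2024,
    min_overlap: int = 10,
) -> InflationPath:
    """Medical-inflation path from a linear CPI-M ~ CPI-U model.

    Fits OLS on the years where both series are observed, predicts CPI-M
    growth for later years from the projected CPI-U path, and accumulates
    multipliers from the base year (actual CPI-M where observed, predicted
    thereafter).
    """
    cpi = cpi.sort_values("year").reset_index(drop=True)
    hist = cpi.dropna(subset=["cpi_m", "cpi_u"])
    if len(hist) < min_overlap:
        raise ValueError(
            f"only {len(hist)} overlapping CPI-M/CPI-U years; >= {min_overlap} required")
    # has_constant="add" keeps the intercept even when CPI-U is constant over
    # the overlap; the pinv solution still predicts correctly at that level
    X = sm.add_constant(hist["cpi_u"], has_constant="add")
    fit = sm.OLS(hist["cpi_m"], X).fit()
    a, b = float(fit.params["const"]), float(fit.params["cpi_u"])

    years = range(base_year + 1, through + 1)
    mult = {base_year: 1.0}
    current = 1.0
    lookup = cpi.set_index("year")
    for year in years:
        if year not in lookup.index:
            raise KeyError(f"CPI table missing year {year}")
        row = lookup.loc[year]
        if not np.isnan(row["cpi_m"]):
            growth = float(row["cpi_m"])
        else:
            if np.isnan(row["cpi_u"]):
                raise KeyError(f"no projected CPI-U for year {year}")
            growth = a + b * float(row["cpi_u"])
        current *= 1.0 + growth
        mult[year] = current
    series = pd.Series(mult)
    series.index.name = "year"
    return InflationPath(series, base_year, source="cpim_estimated")


# --------------------------------------------------------------------------
# enrollment attribution and federal shares
# --------------------------------------------------------------------------

def enrollment_split(
    medicaid_models: dict,
    population: PopulationTable,
    policy: PolicyTables,
    years,
) -> pd.DataFrame:
    """Split projected Medicaid enrollment into traditional vs expansion.

    Expansion enrollees are the excess of the projection under actual
    eligibility thresholds over a counterfactual projection with the adult
    threshold frozen at its pre-expansion level, floored at zero.
    Returns state x year rows with ``enrollees_total/traditional/expansion``
    and the expansion ratio.
    """
    years = sorted(int(y) for y in years)
    actual = project_patients(medicaid_models, population, years)
    cf_pop = counterfactual_population(population, policy)
    counterfactual = project_patients(medicaid_models, cf_pop, years)
    merged = actual.merge(counterfactual, on=["state", "year"],
                          suffixes=("_actual", "_cf"))
    merged["enrollees_expansion"] = np.clip(
        merged["patients_actual"] - merged["patients_cf"], 0.0, None)
    merged["enrollees_total"] = merged["patients_actual"]
    merged["enrollees_traditional"] = (
        merged["enrollees_total"] - merged["enrollees_expansion"])
    with np.errstate(divide="ignore", invalid="ignore"):
        merged["expansion_ratio"] = np.where(
            merged["enrollees_total"] > 0,
            merged["enrollees_expansion"] / merged["enrollees_total"], 0.0)
    return merged[["state", "year", "enrollees_total", "enrollees_traditional",
                   "enrollees_expansion", "expansion_ratio"]]


@dataclass
class FederalShareTable:
    """State x year x group federal/state split of Medicaid revenue.

    Columns: ``group`` in {traditional, expansion}, ``enrollees``,
    ``medicaid_revenue``, ``match_rate`` (FMAP or EFMAP), ``federal``,
    ``state_share``, ``per_capita_expenditure``.
    """

    df: pd.DataFrame

    def group(self, group: str) -> pd.DataFrame:
        return self.df[self.df["group"] == group]


def _shares_from_amounts(rows: list[dict]) -> FederalShareTable:
    df = pd.DataFrame(rows)
    df["federal"] = df["match_rate"] * df["medicaid_revenue"]
    df["state_share"] = df["medicaid_revenue"] - df["federal"]
    with np.errstate(divide="ignore", invalid="ignore"):
        df["per_capita_expenditure"] = np.where(
            df["enrollees"] > 0, df["medicaid_revenue"] / df["enrollees"], 0.0)
    return FederalShareTable(df)


def build_federal_shares(
    baseline: BaselineProjection,
    split: pd.DataFrame,
    policy: PolicyTables,
    fmap_year: int = 2016,
) -> FederalShareTable:
    """Disaggregate projected S0 Medicaid revenue into group federal shares.

    Traditional revenue matches at the state's base-year FMAP; expansion
    revenue at the year's EFMAP. Group revenue splits the payer revenue in
    proportion to enrollees (both groups share the same projected per-capita
    revenue).
    """
    merged = baseline.df.merge(split, on=["state", "year"], how="left")
    if merged["enrollees_total"].isna().any():
        missing = merged[merged["enrollees_total"].isna()][["state", "year"]]
        raise KeyError(f"enrollment split missing rows: {missing.to_dict('records')}")
    rows = []
    for _, r in merged.iterrows():
        fmap = policy.fmap(r["state"], fmap_year)
        efmap = policy.efmap(int(r["year"]))
        for group in GROUPS:
            enr = float(r[f"enrollees_{group}"])
            revenue = enr * float(r["revenue_pc_medicaid"])
            rows.append({
                "state": r["state"], "year": int(r["year"]), "group": group,
                "enrollees": enr, "medicaid_revenue": revenue,
                "match_rate": efmap if group == "expansion" else fmap,
            })
    return _shares_from_amounts(rows)


def historical_federal_shares(
    panel: StatePanel,
    split: pd.DataFrame,
    policy: PolicyTables,
    years=(2015, 2016),
) -> FederalShareTable:
    """Observed-base federal shares for the block-grant / cap base years.

    Observed Medicaid patients and revenue are split between groups by the
    model-based expansion ratio for the same year; the traditional group
    matches at the state's same-year FMAP, the expansion group at EFMAP.
    """
    sub = panel.df[panel.df["year"].isin(list(years))]
    merged = sub.merge(split, on=["state", "year"], how="left")
    if merged["expansion_ratio"].isna().any():
        raise KeyError("enrollment split does not cover the requested base years")
    rows = []
    for _, r in merged.iterrows():
        for group in GROUPS:
            ratio = float(r["expansion_ratio"])
            frac = ratio if group == "expansion" else 1.0 - ratio
            rows.append({
                "state": r["state"], "year": int(r["year"]), "group": group,
                "enrollees": float(r["patients_medicaid"]) * frac,
                "medicaid_revenue": float(r["revenue_medicaid"]) * frac,
                "match_rate": (policy.efmap(int(r["year"])) if group == "expansion"
                               else policy.fmap(r["state"], int(r["year"]))),
            })
    return _shares_from_amounts(rows)


def projected_pc_expenditure(baseline: BaselineProjection, split: pd.DataFrame) -> pd.DataFrame:
    """State x year projected per-capita Medicaid expenditure (all enrollees).

    Input frame for the per-capita cap's deviance adjustment: columns
    ``state, year, enrollees, medicaid_revenue, pc_expenditure``.
    """
    merged = baseline.df.merge(split, on=["state", "year"], how="inner")
    out = pd.DataFrame({
        "state": merged["state"],
        "year": merged["year"],
        "enrollees": merged["enrollees_total"],
        "pc_expenditure": merged["revenue_pc_medicaid"],
    })
    out["medicaid_revenue"] = out["enrollees"] * out["pc_expenditure"]
    return out


# --------------------------------------------------------------------------
# scenarios
# --------------------------------------------------------------------------

def _result_frame(shares: FederalShareTable, scenario: str,
                  scenario_federal: pd.Series, floor_at_zero: bool) -> pd.DataFrame:
    df = shares.df.copy()
    df["scenario"] = scenario
    df["baseline_federal"] = df["federal"]
    df["scenario_federal"] = scenario_federal.to_numpy()
    df["shortfall_abs"] = df["baseline_federal"] - df["scenario_federal"]
    if floor_at_zero:
        df["surplus_abs"] = np.clip(-df["shortfall_abs"], 0.0, None)
        df["shortfall_abs"] = np.clip(df["shortfall_abs"], 0.0, None)
    else:
        df["surplus_abs"] = 0.0
    keep = ["state", "year", "scenario", "group", "enrollees", "medicaid_revenue",
            "baseline_federal", "scenario_federal", "shortfall_abs", "surplus_abs"]
    return df[keep]


def scenario_s0(shares: FederalShareTable) -> pd.DataFrame:
    """Baseline rows: scenario federal equals baseline federal, shortfall 0."""
    return _result_frame(shares, "S0", shares.df["federal"], floor_at_zero=True)


def scenario_s1_efmap_phaseout(
    shares: FederalShareTable,
    policy: PolicyTables,
    base_year: int = 2016,
    floor_at_zero: bool = True,
) -> pd.DataFrame:
    """EFMAP phase-out: expansion-group federal reduced to the traditional rate.

    The reduction equals (EFMAP - FMAP, both at their base-year values) times
    per-capita expenditure times projected expansion enrollees; traditional
    rows and nonexpansion states are unchanged.
    """
    df = shares.df
    expansion_rows = df[(df["group"] == "expansion") & (df["enrollees"] > 0)]
    for state in expansion_rows["state"].unique():
        if not policy.is_expansion(state):
            raise ValueError(f"nonzero expansion enrollees in nonexpansion state {state}")
    reductions = np.zeros(len(df))
    for i, (_, r) in enumerate(df.iterrows()):
        if r["group"] != "expansion":
            continue
        if not policy.is_expansion(r["state"]):
            continue
        differential = policy.efmap(base_year) - policy.fmap(r["state"], base_year)
        reductions[i] = differential * r["per_capita_expenditure"] * r["enrollees"]
    return _result_frame(shares, "S1", df["federal"] - reductions, floor_at_zero)


def scenario_s2_block_grant(
    shares: FederalShareTable,
    base_traditional_federal: pd.Series,
    inflation: InflationPath,
    apply_expansion_phaseout: bool = True,
    floor_at_zero: bool = True,
) -> pd.DataFrame:
    """Block grant: traditional federal fixed at the inflated base-year amount.

    ``base_traditional_federal`` maps state -> base-year traditional federal
    contribution. The scenario contribution is independent of projected
    enrollment. With the expansion phase-out applied (default) the expansion
    group is excluded from the grant base entirely (scenario federal 0);
    disabling it leaves expansion-group contributions at baseline, which
    nests S0 when baseline growth matches the inflation path.
    """
    df = shares.df
    missing = set(df["state"].unique()) - set(base_traditional_federal.index)
    if missing:
        raise KeyError(f"missing base-year traditional federal for state(s) {sorted(missing)}")
    scenario_federal = np.empty(len(df))
    for i, (_, r) in enumerate(df.iterrows()):
        if r["group"] == "traditional":
            scenario_federal[i] = (float(base_traditional_federal.loc[r["state"]])
                                   * inflation.multiplier(int(r["year"])))
        else:
            scenario_federal[i] = 0.0 if apply_expansion_phaseout else r["federal"]
    return _result_frame(shares, "S2", pd.Series(scenario_federal), floor_at_zero)


def scenario_s3_per_capita_cap(
    shares: FederalShareTable,
    base_pc_federal: pd.Series,
    inflation: InflationPath,
    pc_expenditure: pd.DataFrame,
    start_year: int = 2020,
    deviance_mode: str = "annual",
    floor_at_zero: bool = True,
) -> pd.DataFrame:
    """Per-capita cap: federal contribution = capped per-enrollee amount x enrollment.

    ``base_pc_federal`` maps state -> mean base-period (2015-16) traditional
    per-capita federal contribution. The starting cap inflates the base to
    ``start_year`` and applies the state's percent deviance of projected
    per-capita expenditure from the national average in the prior year; with
    ``deviance_mode='annual'`` the deviance multiplier composes every
    subsequent year (the dynamic forecast), with ``'rebase_2020'`` it applies
    once. ``pc_expenditure`` must supply state x year per-capita expenditures
    covering ``start_year - 1`` onward.
    """
    if deviance_mode not in ("annual", "rebase_2020"):
        raise ValueError(f"unknown deviance_mode {deviance_mode!r}")
    df = shares.df
    missing = set(df["state"].unique()) - set(base_pc_federal.index)
    if missing:
        raise KeyError(f"missing base per-capita federal for state(s) {sorted(missing)}")

    pc = pc_expenditure.copy()
    national = (
        pc.groupby("year")
        .apply(lambda g: g["medicaid_revenue"].sum() / g["enrollees"].sum()
               if g["enrollees"].sum() > 0 else np.nan, include_groups=False)
        .rename("national_pc")
    )
    if national.isna().any() or (national <= 0).any():
        raise ValueError("national average per-capita expenditure is zero or undefined")
    pc = pc.merge(national, on="year")
    pc["deviance"] = (pc["pc_expenditure"] - pc["national_pc"]) / pc["national_pc"]
    dev = pc.set_index(["state", "year"])["deviance"]

    years = sorted(df["year"].unique())
    caps: dict[tuple[str, int], float] = {}
    for state in df["state"].unique():
        cap = (float(base_pc_federal.loc[state])
               * inflation.multiplier(start_year)
               * (1.0 + float(dev.loc[(state, start_year - 1)])))
        caps[(state, start_year)] = cap
        for year in years:
            if year <= start_year:
                continue
            growth = 1.0 + inflation.annual_rate(year)
            if deviance_mode == "annual":
                growth *= 1.0 + float(dev.loc[(state, year - 1)])
            cap = cap * growth
            caps[(state, year)] = cap

    scenario_federal = np.array([
        caps[(r["state"], int(r["year"]))] * r["enrollees"]
        for _, r in df.iterrows()
    ])
    return _result_frame(shares, "S3", pd.Series(scenario_federal), floor_at_zero)


# --------------------------------------------------------------------------
# shortfall summary
# --------------------------------------------------------------------------

def compute_shortfall(baseline: BaselineProjection, results: pd.DataFrame) -> pd.DataFrame:
    """Shortfalls in dollars and as percentages of baseline revenues.

    Group rows are scored against the group-attributed baseline Medicaid
    revenue; appended ``group='all'`` rows sum the groups per state x year
    and score against total baseline revenue (all payers plus grants). A zero
    denominator yields an undefined (NaN) percentage with the
    ``pct_undefined`` flag set.
    """
    totals = baseline.df.set_index(["state", "year"])["revenue_total"]
    out = results.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        out["shortfall_pct"] = np.where(
            out["medicaid_revenue"] > 0,
            out["shortfall_abs"] / out["medicaid_revenue"], np.nan)
    out["pct_undefined"] = out["medicaid_revenue"] <= 0

    agg = (
        out.groupby(["state", "year", "scenario"], as_index=False)
        .agg(enrollees=("enrollees", "sum"),
             medicaid_revenue=("medicaid_revenue", "sum"),
             baseline_federal=("baseline_federal", "sum"),
             scenario_federal=("scenario_federal", "sum"),
             shortfall_abs=("shortfall_abs", "sum"),
             surplus_abs=("surplus_abs", "sum"))
    )
    agg["group"] = "all"
    denom = agg.set_index(["state", "year"]).index.map(totals)
    agg["baseline_total_revenue"] = denom.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        agg["shortfall_pct"] = np.where(
            agg["baseline_total_revenue"] > 0,
            agg["shortfall_abs"] / agg["baseline_total_revenue"], np.nan)
    agg["pct_undefined"] = ~(agg["baseline_total_revenue"] > 0)

    out["baseline_total_revenue"] = (
        out.set_index(["state", "year"]).index.map(totals).to_numpy(dtype=float))
    cols = ["state", "year", "scenario", "group", "enrollees", "medicaid_revenue",
            "baseline_federal", "scenario_federal", "shortfall_abs", "surplus_abs",
            "shortfall_pct", "pct_undefined", "baseline_total_revenue"]
    return pd.concat([out[cols], agg[cols]], ignore_index=True).sort_values(
        ["scenario", "state", "year", "group"]).reset_index(drop=True)
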