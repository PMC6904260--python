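"""Shared data model and CSV I/O for the health-center financing pipeline.

All tables are tidy state x year pandas DataFrames wrapped in thin typed
containers. Four table kinds circulate through the pipeline:

* ``StatePanel`` -- UDS-like records of health-center patients, revenues and
  staffing FTEs by payer / service category.
* ``PopulationTable`` -- state population counts by age/sex band plus Medicaid
  eligibility thresholds (as ratios of the federal poverty level).
* ``PolicyTables`` -- FMAP/EFMAP schedules, expansion status, CPI series and
  federal policy constants.
* ``ScenarioResult`` / ``FteImpact`` -- outputs of the scenario engine and the
  capacity module (plain DataFrames with documented columns).

Currency is stored in nominal USD (units of $1). Years are calendar integers
and must form a contiguous range within each state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PAYERS = ["medicaid", "medicare", "private", "self_pay", "other_public"]

SERVICES = [
    "medical_physician",
    "medical_apc",
    "medical_other",
    "dental",
    "mental_health",
    "substance_use",
    "other_professional",
    "nonclinical",
]

#: medical staff types pooled into the single medical cost category
MEDICAL_SERVICES = ["medical_physician", "medical_apc", "medical_other"]

#: cost/revenue-allocation categories (medical staff types pooled)
COST_CATEGORIES = [
    "medical",
    "dental",
    "mental_health",
    "substance_use",
    "other_professional",
    "nonclinical",
]

CLINICAL_CATEGORIES = [c for c in COST_CATEGORIES if c != "nonclinical"]

POP_BANDS = ["age1_18", "age19_49_female", "age19_64", "age65_plus"]
ELIG_GROUPS = ["child", "parents", "adults"]

PANEL_COLUMNS = (
    ["state", "year", "n_health_centers"]
    + [f"patients_{p}" for p in PAYERS]
    + ["patients_total"]
    + [f"revenue_{p}" for p in PAYERS]
    + ["revenue_total", "grant_revenue"]
    + [f"fte_{s}" for s in SERVICES]
    + [f"fte_cost_{s}" for s in SERVICES]
)

POPULATION_COLUMNS = (
    ["state", "year"]
    + [f"pop_{b}" for b in POP_BANDS]
    + [f"elig_{g}" for g in ELIG_GROUPS]
)

POLICY_COLUMNS = [
    "state",
    "year",
    "fmap",
    "efmap",
    "expansion_state",
    "expansion_year",
    "qhp_expansion",
]

CPI_COLUMNS = ["year", "cpi_m", "cpi_u"]

FMAP_FLOOR = 0.50   # statutory minimum federal match
FMAP_CEILING = 0.83  # statutory maximum federal match


class SchemaError(ValueError):
    """A CSV is missing required columns or has an unusable layout."""


class ValidationError(ValueError):
    """A table violates a declared invariant."""


@dataclass(frozen=True)
class Violation:
    state: str | None
    year: int | None
    fieldname: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    def add(self, state, year, fieldname, message) -> None:
        self.violations.append(Violation(state, year, fieldname, message))

    @property
    def ok(self) -> bool:
        return not self.violations

    def raise_if_invalid(self) -> None:
        if not self.ok:
            lines = "; ".join(
                f"({v.state}, {v.year}, {v.fieldname}): {v.message}"
                for v in self.violations[:20]
            )
            raise ValidationError(
                f"{len(self.violations)} invariant violation(s): {lines}"
            )

    def __len__(self) -> int:
        return len(self.violations)


def _check_columns(df: pd.DataFrame, required: Iterable[str], kind: str) -> pd.DataFrame:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{kind} table missing required column(s): {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        logger.warning("%s table: ignoring unknown column(s) %s", kind, extra)
    return df[list(required)].copy()


@dataclass
class StatePanel:
    """State x year panel of health-center patients, revenues and FTEs."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = _check_columns(self.df, PANEL_COLUMNS, "panel")
        self.df = self.df.sort_values(["state", "year"]).reset_index(drop=True)
        self.df["year"] = self.df["year"].astype(int)

    @property
    def states(self) -> list[str]:
        return sorted(self.df["state"].unique().tolist())

    @property
    def years(self) -> list[int]:
        return sorted(self.df["year"].unique().tolist())

    def for_state(self, state: str) -> pd.DataFrame:
        return self.df[self.df["state"] == state].sort_values("year")


@dataclass
class PopulationTable:
    """State x year population bands and Medicaid eligibility thresholds."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = _check_columns(self.df, POPULATION_COLUMNS, "population")
        self.df = self.df.sort_values(["state", "year"]).reset_index(drop=True)
        self.df["year"] = self.df["year"].astype(int)

    @property
    def years(self) -> list[int]:
        return sorted(self.df["year"].unique().tolist())

    def for_state(self, state: str) -> pd.DataFrame:
        return self.df[self.df["state"] == state].sort_values("year")


@dataclass
class PolicyTables:
    """FMAP/EFMAP schedules, expansion flags, CPI series and policy constants.

    ``policy`` holds one row per state x year with the FMAP and the (national)
    EFMAP schedule replicated per row; ``cpi`` holds one row per year with
    CPI-M / CPI-U annual growth fractions.
    """

    policy: pd.DataFrame
    cpi: pd.DataFrame
    block_grant_inflation: float = 0.023
    dra_year: int = 2005
    aca_marketplace_year: int = 2014

    def __post_init__(self) -> None:
        self.policy = _check_columns(self.policy, POLICY_COLUMNS, "policy")
        self.policy = self.policy.sort_values(["state", "year"]).reset_index(drop=True)
        self.cpi = _check_columns(self.cpi, CPI_COLUMNS, "cpi").sort_values("year")
        self.cpi = self.cpi.reset_index(drop=True)

    # -- lookups -----------------------------------------------------------
    def fmap(self, state: str, year: int) -> float:
        sel = self.policy[(self.policy["state"] == state) & (self.policy["year"] == year)]
        if sel.empty:
            raise KeyError(f"no FMAP for {state} {year}")
        return float(sel["fmap"].iloc[0])

    def efmap(self, year: int) -> float:
        sel = self.policy[self.policy["year"] == year]
        if sel.empty:
            raise KeyError(f"no EFMAP for {year}")
        return float(sel["efmap"].iloc[0])

    def is_expansion(self, state: str) -> bool:
        sel = self.policy[self.policy["state"] == state]
        if sel.empty:
            raise KeyError(f"unknown state {state}")
        return bool(sel["expansion_state"].iloc[0])

    def expansion_year(self, state: str) -> int | None:
        sel = self.policy[self.policy["state"] == state]
        if sel.empty:
            raise KeyError(f"unknown state {state}")
        y = sel["expansion_year"].iloc[0]
        return None if pd.isna(y) else int(y)

    def qhp_states(self) -> list[str]:
        flagged = self.policy[self.policy["qhp_expansion"].astype(bool)]
        return sorted(flagged["state"].unique().tolist())

    def validate(self) -> ValidationReport:
        report = ValidationReport()
        pol = self.policy
        bad = pol[(pol["fmap"] <= 0) | (pol["fmap"] >= 1)]
        for _, row in bad.iterrows():
            report.add(row["state"], row["year"], "fmap", f"fmap {row['fmap']} outside (0, 1)")
        exp = pol[pol["expansion_state"].astype(bool)]
        bad = exp[exp["efmap"] < exp["fmap"]]
        for _, row in bad.iterrows():
            report.add(row["state"], row["year"], "efmap", "EFMAP below FMAP in expansion state")
        for col in ("cpi_m", "cpi_u"):
            bad = self.cpi[(self.cpi[col] <= -0.05) | (self.cpi[col] >= 0.20)]
            for _, row in bad.iterrows():
                report.add(None, row["year"], col, f"{col} growth {row[col]} outside (-0.05, 0.20)")
        if not (-0.05 < self.block_grant_inflation < 0.20):
            report.add(None, None, "block_grant_inflation", "inflation outside (-0.05, 0.20)")
        return report


# --------------------------------------------------------------------------
# CSV I/O
# --------------------------------------------------------------------------

_SCHEMAS = {
    "panel": (PANEL_COLUMNS, StatePanel),
    "population": (POPULATION_COLUMNS, PopulationTable),
    "policy": (POLICY_COLUMNS, None),
    "cpi": (CPI_COLUMNS, None),
}


def read_panel(path: str | Path, schema: str):
    """Read and validate one of the four table kinds from CSV.

    ``schema`` is one of ``panel``, ``population``, ``policy``, ``cpi``.
    Returns a typed table (``StatePanel`` / ``PopulationTable``) or a bare
    DataFrame for the policy/cpi kinds, which are assembled into
    :class:`PolicyTables` by :func:`load_policy`. Invariants are checked and
    a :class:`ValidationError` is raised on the first batch of violations.
    """
    if schema not in _SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; expected one of {sorted(_SCHEMAS)}")
    # round_trip parsing keeps write -> read an exact float identity, so a
    # rerun from exported CSVs reproduces the in-memory run bit for bit
    df = pd.read_csv(path, float_precision="round_trip")
    required, cls = _SCHEMAS[schema]
    df = _check_columns(df, required, schema)
    if schema == "panel":
        panel = StatePanel(df)
        validate_panel(panel).raise_if_invalid()
        return panel
    if schema == "population":
        table = PopulationTable(df)
        validate_population(table).raise_if_invalid()
        return table
    return df


def write_table(table, path: str | Path) -> None:
    """Write any table kind back to CSV (UTF-8, comma, header, '.' decimal)."""
    df = table.df if hasattr(table, "df") else table
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def load_policy(policy_path: str | Path, cpi_path: str | Path, **kwargs) -> PolicyTables:
    policy = read_panel(policy_path, "policy")
    cpi = read_panel(cpi_path, "cpi")
    tables = PolicyTables(policy, cpi, **kwargs)
    tables.validate().raise_if_invalid()
    return tables


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------

def _contiguity(report: ValidationReport, df: pd.DataFrame) -> None:
    for state, grp in df.groupby("state"):
        years = np.sort(grp["year"].unique())
        gaps = years[1:][np.diff(years) != 1]
        for y in gaps:
            report.add(state, int(y), "year", "gap in year series (years must be contiguous)")


def validate_panel(panel: StatePanel) -> ValidationReport:
    """Report every invariant violation in a :class:`StatePanel`.

    The report lists (state, year, field) for each violation; an empty report
    means the panel is valid. This never raises -- callers decide.
    """
    report = ValidationReport()
    df = panel.df
    numeric = [c for c in PANEL_COLUMNS if c not in ("state", "year")]
    for col in numeric:
        bad = df[df[col] < 0]
        for _, row in bad.iterrows():
            report.add(row["state"], int(row["year"]), col, f"negative value {row[col]}")
    pat_sum = df[[f"patients_{p}" for p in PAYERS]].sum(axis=1)
    bad = df[~np.isclose(pat_sum, df["patients_total"], rtol=1e-9, atol=1e-6)]
    for idx, row in bad.iterrows():
        report.add(row["state"], int(row["year"]), "patients_total",
                   f"total {row['patients_total']} != sum of payer patients {pat_sum[idx]}")
    rev_sum = df[[f"revenue_{p}" for p in PAYERS]].sum(axis=1)
    bad = df[~np.isclose(rev_sum, df["revenue_total"], rtol=1e-9, atol=1e-4)]
    for idx, row in bad.iterrows():
        report.add(row["state"], int(row["year"]), "revenue_total",
                   f"total {row['revenue_total']} != sum of payer revenues {rev_sum[idx]}")
    _contiguity(report, df)
    return report


def validate_population(table: PopulationTable) -> ValidationReport:
    report = ValidationReport()
    df = table.df
    for col in [f"pop_{b}" for b in POP_BANDS] + [f"elig_{g}" for g in ELIG_GROUPS]:
        bad = df[df[col] < 0]
        for _, row in bad.iterrows():
            report.add(row["state"], int(row["year"]), col, f"negative value {row[col]}")
    bad = df[df["pop_age19_49_female"] > df["pop_age19_64"]]
    for _, row in bad.iterrows():
        report.add(row["state"], int(row["year"]), "pop_age19_49_female",
                   "female 19-49 band exceeds total 19-64 band")
    _contiguity(report, df)
    return report


# --------------------------------------------------------------------------
# Sample restriction
# --------------------------------------------------------------------------

def exclude_qhp_states(panel: StatePanel, policy: PolicyTables) -> StatePanel:
    """Drop states whose expansion runs through marketplace QHP subsidies.

    In such states (New Hampshire and Iowa in the real data) expansion-group
    revenue is booked as private-plan revenue, which would skew Medicaid
    rollback projections, so they are removed from the quantitative sample.
    """
    panel_states = set(panel.states)
    known = set(policy.policy["state"].unique())
    missing = panel_states - known
    if missing:
        raise KeyError(f"policy table lacks qhp_expansion flags for state(s): {sorted(missing)}")
    flagged = [s for s in policy.qhp_states() if s in panel_states]
    if flagged:
        logger.info("excluding QHP-expansion state(s) from analysis: %s", flagged)
    out = panel.df[~panel.df["state"].isin(flagged)].reset_index(drop=True)
    if out.empty:
        logger.warning("all states excluded by the QHP rule; returning an empty panel")
    return StatePanel(out)
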