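"""Baseline (S0) model fits and 2020-2024 projections.

Three model families are fitted separately by state on the 2000-2016 panel:

1. **Patient models** -- payer patient counts regressed (no intercept) on
   population-band x eligibility-threshold products; private/self-pay add a
   marketplace level dummy for years >= 2014.
2. **Per-capita revenue models** -- a dynamic linear model
   ``R_t = a0 + a1 R_{t-1} + a2 t + a3 t*ACA + a4 t*DRA`` fitted on
   lead/lag-smoothed per-capita revenues; ACA is the state's own
   expansion-year indicator, DRA flags years after 2005.
3. **FTE cost models** -- service-category cost regressed on staff-mix FTE
   counts scaled by compound labor-cost growth ``(1+r)^(t-2000)``, with ``r``
   profiled on a coarse grid and refined.

Baseline projections recombine the three: projected revenue per payer =
projected patients x projected per-capita revenue, and baseline FTEs divide
category-allocated revenue (2016 allocation shares) by projected per-FTE
costs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import statsmodels.api as sm

from .core_data import (
    COST_CATEGORIES,
    MEDICAL_SERVICES,
    PAYERS,
    PolicyTables,
    PopulationTable,
    StatePanel,
)
from .synthetic import patient_design

logger = logging.getLogger(__name__)

TREND_ORIGIN = 2000  # trend variable is t - 2000 for conditioning

REVENUE_TERMS = ["const", "lag", "trend", "trend_aca", "trend_dra"]


class InsufficientDataError(ValueError):
    """Too few usable years to fit the requested model."""


class RankDeficientError(ValueError):
    """The design matrix is rank deficient; names the collinear regressors."""


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    if X.shape[0] < X.shape[1]:
        raise InsufficientDataError(
            f"{X.shape[0]} usable rows for {X.shape[1]} regressors"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = scipy.linalg.qr(X, pivoting=True)
        collinear = [names[j] for j in piv[rank:]]
        raise RankDeficientError(f"design matrix rank {rank} < {X.shape[1]}; "
                                 f"collinear regressor(s): {collinear}")


# --------------------------------------------------------------------------
# patient models
# --------------------------------------------------------------------------

@dataclass
class PatientModelCoeffs:
    payer: str
    state: str
    coeffs: pd.Series            # by regressor name
    conf_int: pd.DataFrame       # 95% CI, columns [lower, upper]
    resid_sd: float
    n: int
    add_intercept: bool = False


def fit_patient_model(
    panel: StatePanel,
    population: PopulationTable,
    payer: str,
    add_intercept: bool = False,
    min_years: int = 7,
) -> dict[str, PatientModelCoeffs]:
    """Least-squares patient-count model for one payer, separately by state.

    The Medicaid specification regresses patient counts on the five
    eligibility-scaled population terms with no intercept (a flag adds one);
    other payers use the raw bands, with the 2014+ marketplace dummy for
    private and self-pay.
    """
    models: dict[str, PatientModelCoeffs] = {}
    for state in panel.states:
        sub = panel.for_state(state)
        pop = population.for_state(state)
        merged = sub.merge(pop, on=["state", "year"], how="left")
        if merged[[f"pop_{c}" for c in ("age1_18",)]].isna().any().any():
            raise KeyError(f"population table missing years for state {state}")
        n = len(merged)
        X = patient_design(merged, payer)
        if add_intercept:
            X = sm.add_constant(X)
        if n < max(min_years, X.shape[1] + 2):
            raise InsufficientDataError(
                f"state {state}: {n} years < required {max(min_years, X.shape[1] + 2)}"
            )
        _check_rank(X.to_numpy(), list(X.columns))
        y = merged[f"patients_{payer}"]
        fit = sm.OLS(y, X).fit()
        models[state] = PatientModelCoeffs(
            payer=payer,
            state=state,
            coeffs=fit.params,
            conf_int=fit.conf_int().rename(columns={0: "lower", 1: "upper"}),
            resid_sd=float(np.sqrt(fit.scale)),
            n=n,
            add_intercept=add_intercept,
        )
    return models


def project_patients(
    models: dict[str, PatientModelCoeffs],
    population: PopulationTable,
    years: list[int],
) -> pd.DataFrame:
    """Predicted patient counts per state x year, clamped at zero.

    Returns columns ``state, year, patients``; negative raw predictions are
    clamped to 0 with a logged count.
    """
    missing = set(years) - set(population.years)
    if missing:
        raise KeyError(f"population table missing projection year(s) {sorted(missing)}")
    frames = []
    n_clamped = 0
    for state, model in models.items():
        pop = population.for_state(state)
        pop = pop[pop["year"].isin(years)].reset_index(drop=True)
        X = patient_design(pop, model.payer)
        if model.add_intercept:
            X = sm.add_constant(X, has_constant="add")
        raw = X.to_numpy() @ model.coeffs.to_numpy()
        n_clamped += int((raw < 0).sum())
        frames.append(pd.DataFrame({
            "state": state, "year": pop["year"], "patients": np.clip(raw, 0.0, None),
        }))
    if n_clamped:
        logger.info("project_patients: clamped %d negative prediction(s) to 0", n_clamped)
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# per-capita revenue models
# --------------------------------------------------------------------------

def smooth_per_capita_revenue(series):
    """Centered moving average with one lead and one lag.

    Interior values are 3-term means; the two endpoints use the available
    2-term mean. Accepts a sequence of length >= 3 and returns an ndarray
    (or a Series with the original index if given one).
    """
    values = np.asarray(series, dtype=float)
    if values.ndim != 1 or len(values) < 3:
        raise ValueError("series must be one-dimensional with length >= 3")
    out = np.empty_like(values)
    out[1:-1] = (values[:-2] + values[1:-1] + values[2:]) / 3.0
    out[0] = (values[0] + values[1]) / 2.0
    out[-1] = (values[-2] + values[-1]) / 2.0
    if isinstance(series, pd.Series):
        return pd.Series(out, index=series.index)
    return out


def _centered_mean3(values: np.ndarray) -> np.ndarray:
    """Interior 3-term centered means; endpoints returned as NaN."""
    out = np.full_like(np.asarray(values, dtype=float), np.nan)
    out[1:-1] = (values[:-2] + values[1:-1] + values[2:]) / 3.0
    return out


@dataclass
class RevenueModelCoeffs:
    payer: str
    state: str
    coeffs: pd.Series            # over REVENUE_TERMS; dropped terms are 0
    conf_int: pd.DataFrame
    dropped: list[str]
    explosive: bool
    resid_sd: float
    n: int
    expansion_year: int | None
    dra_year: int
    trend_origin: int = TREND_ORIGIN

    @property
    def alpha(self) -> np.ndarray:
        return self.coeffs.reindex(REVENUE_TERMS, fill_value=0.0).to_numpy()


def per_capita_revenue_series(panel: StatePanel, state: str, payer: str) -> pd.Series:
    sub = panel.for_state(state)
    patients = sub[f"patients_{payer}"].to_numpy()
    revenue = sub[f"revenue_{payer}"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        pc = np.where(patients > 0, revenue / patients, 0.0)
    return pd.Series(pc, index=pd.Index(sub["year"].to_numpy(), name="year"))


def fit_revenue_model(
    panel: StatePanel,
    policy: PolicyTables,
    payer: str,
    smooth: bool = True,
) -> dict[str, RevenueModelCoeffs]:
    """Dynamic per-capita revenue model for one payer, separately by state.

    The dependent series is lead/lag smoothed before fitting. Because the
    centered moving average of a series obeying the recursion obeys the same
    recursion with the policy-interaction regressors replaced by their own
    centered window means, the interaction regressors are smoothed with the
    identical filter, and rows whose dependent value or lag is a partial
    endpoint window are dropped. States where the ACA interaction column is
    identically zero (nonexpansion states) have the term dropped with a
    warning; a fitted lag coefficient >= 1 sets the explosive-forecast flag.
    """
    models: dict[str, RevenueModelCoeffs] = {}
    for state in panel.states:
        pc = per_capita_revenue_series(panel, state, payer)
        years = pc.index.to_numpy()
        tau = years - TREND_ORIGIN
        exp_year = policy.expansion_year(state) if payer == "medicaid" else None
        aca = ((years >= exp_year).astype(float)
               if exp_year is not None else np.zeros(len(years)))
        dra = (years > policy.dra_year).astype(float)
        t_aca = tau * aca
        t_dra = tau * dra

        if smooth:
            y_all = smooth_per_capita_revenue(pc).to_numpy()
            x_aca = _centered_mean3(t_aca)
            x_dra = _centered_mean3(t_dra)
            # usable rows: both S_t and its lag are full 3-term windows
            idx = np.arange(2, len(years) - 1)
        else:
            y_all = pc.to_numpy()
            x_aca = t_aca.astype(float)
            x_dra = t_dra.astype(float)
            idx = np.arange(1, len(years))
        if len(idx) < 3:
            raise InsufficientDataError(
                f"state {state}: only {len(idx)} usable rows after smoothing/lagging"
            )

        X = pd.DataFrame({
            "const": 1.0,
            "lag": y_all[idx - 1],
            "trend": tau[idx].astype(float),
            "trend_aca": x_aca[idx],
            "trend_dra": x_dra[idx],
        })
        y = pd.Series(y_all[idx])

        dropped = []
        for term in ("trend_aca", "trend_dra"):
            if np.allclose(X[term], 0.0):
                logger.warning("state %s payer %s: %s column is all zero; term dropped",
                               state, payer, term)
                X = X.drop(columns=[term])
                dropped.append(term)
        _check_rank(X.to_numpy(), list(X.columns))
        fit = sm.OLS(y, X).fit()
        coeffs = fit.params.reindex(REVENUE_TERMS, fill_value=0.0)
        explosive = bool(abs(coeffs["lag"]) >= 1.0)
        if explosive:
            logger.warning("state %s payer %s: |lag coefficient| %.3f >= 1; "
                           "forecasts will be explosive", state, payer, coeffs["lag"])
        models[state] = RevenueModelCoeffs(
            payer=payer,
            state=state,
            coeffs=coeffs,
            conf_int=fit.conf_int().rename(columns={0: "lower", 1: "upper"}),
            dropped=dropped,
            explosive=explosive,
            resid_sd=float(np.sqrt(fit.scale)),
            n=len(y),
            expansion_year=exp_year,
            dra_year=policy.dra_year,
        )
    return models


def project_per_capita_revenue(
    coeffs: RevenueModelCoeffs,
    last_observed: float,
    years: list[int],
) -> pd.Series:
    """Dynamic forecast of the per-capita revenue recursion.

    Seeds the recursion from ``last_observed`` (the value for the year
    preceding the first projection year) and iterates
    ``R_t = a0 + a1 R_{t-1} + a2 t + a3 t*ACA_t + a4 t*DRA_t``, clamping at 0.
    """
    a0, a1, a2, a3, a4 = coeffs.alpha
    values = []
    prev = float(last_observed)
    for year in years:
        tau = year - coeffs.trend_origin
        aca = 1.0 if (coeffs.expansion_year is not None and year >= coeffs.expansion_year) else 0.0
        dra = 1.0 if year > coeffs.dra_year else 0.0
        value = a0 + a1 * prev + a2 * tau + a3 * tau * aca + a4 * tau * dra
        value = max(value, 0.0)
        values.append(value)
        prev = value
    return pd.Series(values, index=pd.Index(list(years), name="year"))


# --------------------------------------------------------------------------
# FTE cost models
# --------------------------------------------------------------------------

@dataclass
class FteCostCoeffs:
    category: str
    state: str
    beta0: float
    betas: pd.Series             # per staff-mix FTE regressor
    labor_growth: float
    conf_int: pd.DataFrame       # CIs for (beta0, betas), conditional on r
    resid_sd: float
    n: int
    trend_origin: int = TREND_ORIGIN
    fte_columns: list[str] = field(default_factory=list)

    def predict(self, fte: pd.DataFrame, years) -> np.ndarray:
        """Predicted category cost for given staff FTE counts and years."""
        tau = np.asarray(years) - self.trend_origin
        X = fte[self.fte_columns].to_numpy()
        return self.beta0 + (X @ self.betas.to_numpy()) * (1.0 + self.labor_growth) ** tau


def _fte_joint_conf_int(y, F, tau, beta, r_hat, names):
    """95% CIs for (beta0, betas, labor_growth) from the joint NLS Jacobian.

    The cost model is nonlinear in r; conditioning on the profiled r would
    understate the betas' uncertainty, so the covariance comes from the full
    Jacobian ``[1, F*(1+r)^tau, (F@betas)*tau*(1+r)^(tau-1)]``.
    """
    import scipy.stats

    growth = (1.0 + r_hat) ** tau
    X = F * growth[:, None]
    dr = (F @ beta[1:]) * tau * (1.0 + r_hat) ** (tau - 1)
    J = np.column_stack([np.ones(len(y)), X, dr])
    p = J.shape[1]
    resid = y - (beta[0] + (F @ beta[1:]) * growth)
    dof = max(len(y) - p, 1)
    s2 = float(resid @ resid) / dof
    # the profile is nearly flat in r, so J'J is close to singular along that
    # direction; equilibrate before inverting so the flat direction yields the
    # appropriately *wide* interval rather than a truncated one
    JtJ = J.T @ J
    d = 1.0 / np.sqrt(np.diag(JtJ))
    cov = s2 * (d[:, None] * np.linalg.inv(d[:, None] * JtJ * d[None, :]) * d[None, :])
    se = np.sqrt(np.abs(np.diag(cov)))
    tcrit = scipy.stats.t.ppf(0.975, dof)
    center = np.append(beta, r_hat)
    frame = pd.DataFrame(
        {"lower": center - tcrit * se, "upper": center + tcrit * se},
        index=names + ["labor_growth"])
    return frame, float(np.sqrt(s2))


def _category_cost_and_fte(panel_df: pd.DataFrame, category: str):
    if category == "medical":
        cost = panel_df[[f"fte_cost_{s}" for s in MEDICAL_SERVICES]].sum(axis=1)
        fte_cols = [f"fte_{s}" for s in MEDICAL_SERVICES]
    else:
        cost = panel_df[f"fte_cost_{category}"]
        fte_cols = [f"fte_{category}"]
    return cost, fte_cols


def fit_fte_cost_model(
    panel: StatePanel,
    category: str,
    labor_growth: float | None = None,
    growth_bounds: tuple[float, float] = (-0.02, 0.10),
) -> dict[str, FteCostCoeffs]:
    """Staff-mix FTE cost model for one service category, separately by state.

    Fits ``C_t = b0 + (sum_i b_i FTE_i,t) * (1+r)^(t-2000)`` by profiling the
    labor-growth rate ``r`` on a coarse grid (5e-3 steps) and refining the
    best grid point with bounded scalar minimization; ``labor_growth``
    supplies ``r`` directly and skips the search. States where the category
    FTE count is zero in every year are skipped with a warning.
    """
    if category not in COST_CATEGORIES:
        raise KeyError(f"unknown cost category {category!r}")
    models: dict[str, FteCostCoeffs] = {}
    for state in panel.states:
        sub = panel.for_state(state)
        y, fte_cols = _category_cost_and_fte(sub, category)
        y = y.to_numpy(dtype=float)
        F = sub[fte_cols].to_numpy(dtype=float)
        tau = sub["year"].to_numpy() - TREND_ORIGIN
        if np.allclose(F, 0.0):
            logger.warning("state %s: %s FTEs are zero in all years; model skipped",
                           state, category)
            continue

        def _ols(r: float):
            X = np.column_stack([np.ones(len(y)), F * (1.0 + r) ** tau[:, None]])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            return float(resid @ resid), beta, X

        if labor_growth is not None:
            r_hat = float(labor_growth)
        else:
            grid = np.arange(growth_bounds[0], growth_bounds[1] + 1e-12, 0.005)
            sses = [_ols(r)[0] for r in grid]
            r0 = grid[int(np.argmin(sses))]
            res = scipy.optimize.minimize_scalar(
                lambda r: _ols(r)[0],
                bounds=(max(r0 - 0.005, growth_bounds[0]),
                        min(r0 + 0.005, growth_bounds[1])),
                method="bounded",
                options={"xatol": 1e-12},
            )
            r_hat = float(res.x)

        _, beta, X = _ols(r_hat)
        names = ["beta0"] + fte_cols
        fit = sm.OLS(y, pd.DataFrame(X, columns=names)).fit()
        if labor_growth is not None:
            # r supplied: conditional linear inference is exact
            conf_int = fit.conf_int().rename(columns={0: "lower", 1: "upper"})
            resid_sd = float(np.sqrt(fit.scale))
        else:
            # r estimated: joint nonlinear-least-squares (delta method)
            # intervals, so the betas' uncertainty reflects the profiled r
            conf_int, resid_sd = _fte_joint_conf_int(
                y, F, tau, fit.params.to_numpy(), r_hat, names)
        models[state] = FteCostCoeffs(
            category=category,
            state=state,
            beta0=float(fit.params["beta0"]),
            betas=fit.params.drop("beta0"),
            labor_growth=r_hat,
            conf_int=conf_int,
            resid_sd=resid_sd,
            n=len(y),
            fte_columns=fte_cols,
        )
    return models


# --------------------------------------------------------------------------
# baseline projection
# --------------------------------------------------------------------------

@dataclass
class BaselineProjection:
    """Projected S0 panel: one row per state x projection year.

    Columns: ``patients_<payer>``, ``revenue_pc_<payer>``, ``revenue_<payer>``,
    ``revenue_total`` (all payers plus grants held at their last observed
    level), ``grant_revenue``, ``alloc_share_<category>`` (last-observed-year
    revenue allocation shares), ``per_fte_cost_<category>`` and
    ``baseline_fte_<category>``.
    """

    df: pd.DataFrame
    base_year: int               # last observed panel year (allocation/grant base)

    @property
    def years(self) -> list[int]:
        return sorted(self.df["year"].unique().tolist())

    @property
    def states(self) -> list[str]:
        return sorted(self.df["state"].unique().tolist())

    def for_state(self, state: str) -> pd.DataFrame:
        return self.df[self.df["state"] == state].sort_values("year")


def allocation_shares(panel: StatePanel, base_year: int) -> pd.DataFrame:
    """Service-category revenue allocation shares from base-year FTE costs.

    Shares are normalized to sum to one per state; a renormalization beyond
    rounding noise is logged.
    """
    base = panel.df[panel.df["year"] == base_year]
    if base.empty:
        raise KeyError(f"panel has no rows for base year {base_year}")
    rows = []
    for _, row in base.iterrows():
        costs = {}
        for cat in COST_CATEGORIES:
            if cat == "medical":
                costs[cat] = sum(row[f"fte_cost_{s}"] for s in MEDICAL_SERVICES)
            else:
                costs[cat] = row[f"fte_cost_{cat}"]
        total = sum(costs.values())
        if total <= 0:
            raise ValueError(f"state {row['state']}: base-year FTE costs are all zero")
        shares = {cat: c / total for cat, c in costs.items()}
        rows.append({"state": row["state"],
                     **{f"alloc_share_{cat}": shares[cat] for cat in COST_CATEGORIES}})
    return pd.DataFrame(rows)


def project_baseline(
    panel: StatePanel,
    population: PopulationTable,
    policy: PolicyTables,
    patient_models: dict[str, dict],
    revenue_models: dict[str, dict],
    fte_models: dict[str, dict],
    years: list[int],
    smooth_seed: bool = False,
) -> BaselineProjection:
    """Combine the fitted models into the baseline (S0) projection.

    ``patient_models`` / ``revenue_models`` map payer -> {state: coeffs};
    ``fte_models`` maps category -> {state: coeffs}. The per-capita revenue
    recursion runs from the year after the panel ends through ``max(years)``
    and is seeded from the last observed per-capita value (optionally the
    smoothed one). Revenue allocation shares and grant revenue are held at
    the last observed panel year.
    """
    base_year = max(panel.years)
    years = sorted(int(y) for y in years)
    if years[0] <= base_year:
        raise ValueError(f"projection years must start after the panel end {base_year}")
    recursion_years = list(range(base_year + 1, years[-1] + 1))

    shares = allocation_shares(panel, base_year).set_index("state")
    base_rows = panel.df[panel.df["year"] == base_year].set_index("state")

    patients = {
        payer: project_patients(models, population, recursion_years)
        .set_index(["state", "year"])["patients"]
        for payer, models in patient_models.items()
    }

    frames = []
    for state in panel.states:
        sub = panel.for_state(state)
        out = pd.DataFrame({"state": state, "year": recursion_years})
        total_patient_revenue = np.zeros(len(recursion_years))
        for payer in PAYERS:
            pc_obs = per_capita_revenue_series(panel, state, payer)
            seed_value = (smooth_per_capita_revenue(pc_obs).iloc[-1]
                          if smooth_seed else pc_obs.iloc[-1])
            pc_proj = project_per_capita_revenue(
                revenue_models[payer][state], seed_value, recursion_years)
            pats = patients[payer].loc[state].reindex(recursion_years).to_numpy()
            out[f"patients_{payer}"] = pats
            out[f"revenue_pc_{payer}"] = pc_proj.to_numpy()
            out[f"revenue_{payer}"] = pats * pc_proj.to_numpy()
            total_patient_revenue += out[f"revenue_{payer}"].to_numpy()
        grant = float(base_rows.loc[state, "grant_revenue"])
        out["grant_revenue"] = grant
        out["revenue_total"] = total_patient_revenue + grant

        base_fte = sub[sub["year"] == base_year]
        for cat in COST_CATEGORIES:
            model = fte_models[cat].get(state)
            share = float(shares.loc[state, f"alloc_share_{cat}"])
            out[f"alloc_share_{cat}"] = share
            if model is None:
                out[f"per_fte_cost_{cat}"] = np.nan
                out[f"baseline_fte_{cat}"] = 0.0
                continue
            fte_count = float(base_fte[model.fte_columns].sum(axis=1).iloc[0])
            pred_cost = model.predict(base_fte, np.array(recursion_years))
            if fte_count <= 0 or np.any(pred_cost <= 0):
                raise ValueError(
                    f"state {state} category {cat}: nonpositive projected FTE cost")
            per_fte = pred_cost / fte_count
            out[f"per_fte_cost_{cat}"] = per_fte
            out[f"baseline_fte_{cat}"] = out["revenue_total"] * share / per_fte
        frames.append(out)

    df = pd.concat(frames, ignore_index=True)
    df = df[df["year"].isin(years)].reset_index(drop=True)
    return BaselineProjection(df, base_year=base_year)


def counterfactual_population(
    population: PopulationTable, policy: PolicyTables
) -> PopulationTable:
    """Population table with adult eligibility frozen at pre-expansion levels.

    Used to attribute projected Medicaid patients to the expansion group:
    expansion enrollees = projection with actual thresholds minus projection
    with the adult threshold held at its last pre-expansion value, floored
    at zero. Nonexpansion states are unchanged.
    """
    df = population.df.copy()
    for state in df["state"].unique():
        exp_year = policy.expansion_year(state)
        if exp_year is None:
            continue
        mask = df["state"] == state
        pre = df[mask & (df["year"] == exp_year - 1)]
        if pre.empty:
            raise KeyError(f"no pre-expansion year {exp_year - 1} for state {state}")
        frozen = float(pre["elig_adults"].iloc[0])
        df.loc[mask & (df["year"] >= exp_year), "elig_adults"] = frozen
    return PopulationTable(df)
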