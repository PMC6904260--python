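"""Synthetic UDS-like data with known ground truth.

Generates state x year panels of health-center patients, revenues and
staffing costs, population tables with Medicaid eligibility thresholds, and
policy tables (FMAP/EFMAP schedules, expansion status, CPI series), all from
a single master seed. The data-generating process mirrors the three model
families the pipeline fits:

* patient counts are a no-intercept linear combination of population-band x
  eligibility-threshold regressors plus truncated Gaussian noise;
* per-capita revenues follow a dynamic linear recursion with trend and
  policy-indicator interaction terms, with Gaussian innovations feeding the
  realized lag forward;
* service-category FTE costs are a staff-mix linear predictor scaled by
  compound labor-cost growth ``(1+r)**(t-2000)``.

Because each state's own regression only identifies the eligibility-scaled
regressors when thresholds move over time, the generator gives every state a
small set of piecewise-constant threshold steps (as real states legislated
over 2000-2016) in addition to the expansion-year jump of the adult
threshold to 1.38 x FPL in expansion states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import (
    COST_CATEGORIES,
    MEDICAL_SERVICES,
    PAYERS,
    POP_BANDS,
    SERVICES,
    PolicyTables,
    PopulationTable,
    StatePanel,
)

logger = logging.getLogger(__name__)

#: band shares of total state population (children, women 19-49, adults 19-64, 65+)
_BAND_SHARES = {
    "age1_18": 0.24,
    "age19_49_female": 0.20,
    "age19_64": 0.60,
    "age65_plus": 0.15,
}

#: health-center staffing FTEs per million state residents in 2000
_FTE_BASE_PER_M = {
    "medical_physician": 10.0,
    "medical_apc": 8.0,
    "medical_other": 20.0,
    "dental": 6.0,
    "mental_health": 4.0,
    "substance_use": 1.5,
    "other_professional": 15.0,
    "nonclinical": 18.0,
}

#: federal EFMAP schedule: 100% through 2016, stepping down to 90% by 2020
_EFMAP_SCHEDULE = {2014: 1.00, 2015: 1.00, 2016: 1.00, 2017: 0.95, 2018: 0.94,
                   2019: 0.93}
_EFMAP_FLOOR = 0.90


def _default_patient_coeffs() -> dict[str, np.ndarray]:
    # Medicaid: [P(1-18)*E_child, P(19-49,F)*E_parents, P(19-64)*E_adults,
    #            P(65+)*E_adults, P(19-64)]; other payers: raw bands only.
    return {
        "medicaid": np.array([0.012, 0.020, 0.010, 0.008, 0.004]),
        "medicare": np.array([0.0005, 0.001, 0.001, 0.015]),
        "private": np.array([0.004, 0.005, 0.004, 0.001]),
        "self_pay": np.array([0.006, 0.008, 0.006, 0.002]),
        "other_public": np.array([0.001, 0.002, 0.001, 0.001]),
    }


def _default_marketplace_dummy() -> dict[str, float]:
    # level shift (persons) from 2014 on: the marketplace adds privately
    # insured patients and moves uninsured people off self-pay
    return {"private": 3000.0, "self_pay": -4000.0}


def _default_revenue_coeffs() -> dict[str, np.ndarray]:
    # (alpha0, alpha1 lag, alpha2 trend, alpha3 trend*ACA, alpha4 trend*DRA);
    # per-capita USD, trend in years since the panel start
    return {
        "medicaid": np.array([400.0, 0.5, 4.0, 3.0, 2.0]),
        "medicare": np.array([350.0, 0.5, 3.0, 0.0, 1.5]),
        "private": np.array([120.0, 0.5, 2.0, 0.0, 1.0]),
        "self_pay": np.array([20.0, 0.5, 0.5, 0.0, 0.2]),
        "other_public": np.array([2000.0, 0.6, 30.0, 0.0, 10.0]),
    }


def _default_fte_cost_coeffs() -> dict[str, dict]:
    # beta0: fixed cost (equipment/depreciation); betas: USD per staff FTE
    return {
        "medical": {"beta0": 2.0e5, "betas": np.array([2.4e5, 1.3e5, 0.9e5])},
        "dental": {"beta0": 1.0e5, "betas": np.array([1.3e5])},
        "mental_health": {"beta0": 0.5e5, "betas": np.array([1.1e5])},
        "substance_use": {"beta0": 0.2e5, "betas": np.array([1.0e5])},
        "other_professional": {"beta0": 1.0e5, "betas": np.array([0.9e5])},
        "nonclinical": {"beta0": 1.5e5, "betas": np.array([0.7e5])},
    }


def _default_noise_sd() -> dict[str, float]:
    return {"patients": 800.0, "revenue_pc": 8.0, "fte_cost": 1.0e5, "cpi": 0.002}


@dataclass
class SyntheticConfig:
    """Ground-truth parameters for the synthetic study population.

    Defaults emulate an 8-state sample observed 2000-2016 with projections
    through 2024: two states expand Medicaid via marketplace QHP subsidies
    (and are excluded from analysis, as New Hampshire and Iowa are in the
    real data), three expand conventionally in 2014, and three never expand.
    """

    n_states: int = 8
    n_qhp_states: int = 2
    expansion_share: float = 0.5  # share of non-QHP states that expand
    expansion_year_default: int = 2014
    history_years: tuple[int, int] = (2000, 2016)
    projection_years: tuple[int, int] = (2017, 2024)
    true_patient_coeffs: dict = field(default_factory=_default_patient_coeffs)
    marketplace_dummy: dict = field(default_factory=_default_marketplace_dummy)
    true_revenue_coeffs: dict = field(default_factory=_default_revenue_coeffs)
    true_fte_cost_coeffs: dict = field(default_factory=_default_fte_cost_coeffs)
    labor_growth_range: tuple[float, float] = (0.01, 0.05)
    fte_growth_range: tuple[float, float] = (0.03, 0.06)
    pop_growth_range: tuple[float, float] = (0.002, 0.015)
    pop_base_range: tuple[float, float] = (1.0e6, 8.0e6)
    pop_growth: dict | None = None  # optional per-state override (one rate, all bands)
    noise_sd: dict = field(default_factory=_default_noise_sd)
    cpi_a: float = 0.012          # CPI-M = a + b * CPI-U + noise
    cpi_b: float = 0.9
    cpi_u_mean: float = 0.02
    cpi_u_sd: float = 0.004
    dra_year: int = 2005          # DRA indicator on for years after this
    block_grant_inflation: float = 0.023
    state_clustered_noise: bool = False  # per-state residual SD multipliers
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if self.n_qhp_states >= self.n_states:
            raise ValueError("n_qhp_states must leave at least one analysis state")
        for channel, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError(f"noise_sd[{channel}] must be >= 0")
        for payer, alpha in self.true_revenue_coeffs.items():
            if abs(alpha[1]) >= 1:
                raise ValueError(
                    f"revenue lag coefficient for {payer} is {alpha[1]}; "
                    "|alpha1| < 1 required for a stationary recursion"
                )
        lo, hi = self.labor_growth_range
        if not (-0.02 <= lo <= hi <= 0.10):
            raise ValueError("labor_growth_range must lie within (-0.02, 0.10)")

    @property
    def states(self) -> list[str]:
        # synthetic two-letter codes ZA, ZB, ... (avoid real postal codes)
        return [f"Z{chr(ord('A') + i)}" for i in range(self.n_states)]

    @property
    def all_years(self) -> list[int]:
        return list(range(self.history_years[0], self.projection_years[1] + 1))

    def child_rng(self, channel: str) -> np.random.Generator:
        """Deterministic per-channel generator derived from the master seed."""
        order = ["population", "policy", "state_params", "patients", "revenue",
                 "fte", "cpi", "fte_levels"]
        ss = np.random.SeedSequence(self.seed).spawn(len(order))
        return np.random.default_rng(ss[order.index(channel)])


@dataclass
class GroundTruth:
    """Realized generating parameters and noiseless latent series."""

    patient_coeffs: dict
    marketplace_dummy: dict
    revenue_coeffs: dict
    fte_cost_coeffs: dict        # per category: beta0, betas, labor_growth per state
    expansion_states: dict       # state -> expansion year or None
    qhp_states: list
    latent: pd.DataFrame         # noiseless panel (same columns as StatePanel)
    latent_revenue_pc: pd.DataFrame  # state, year, payer, per-capita revenue
    truncation_rate: float


# --------------------------------------------------------------------------
# per-state parameter draws (shared by population, panel, ground truth)
# --------------------------------------------------------------------------

def _state_attributes(config: SyntheticConfig) -> pd.DataFrame:
    """Base population, band growth rates and eligibility steps per state."""
    rng = config.child_rng("population")
    rows = []
    for state in config.states:
        base = rng.uniform(*config.pop_base_range)
        if config.pop_growth and state in config.pop_growth:
            g = float(config.pop_growth[state])
            growth = {band: g for band in POP_BANDS}
        else:
            growth = {band: rng.uniform(*config.pop_growth_range) for band in POP_BANDS}
        # pre-expansion eligibility levels plus one legislated step per group
        # at a state-specific year; the within-state threshold variation is
        # what identifies the eligibility-scaled regressors per state
        rows.append({
            "state": state,
            "pop_base": base,
            **{f"g_{band}": growth[band] for band in POP_BANDS},
            "elig_child_0": rng.uniform(1.6, 2.2),
            "elig_child_1": rng.uniform(1.8, 2.6),
            "elig_child_step": int(rng.integers(2004, 2010)),
            "elig_parents_0": rng.uniform(0.4, 0.8),
            "elig_parents_1": rng.uniform(0.5, 0.9),
            "elig_parents_step": int(rng.integers(2005, 2012)),
            "elig_adults_0": rng.uniform(0.2, 0.5),
            "elig_adults_1": rng.uniform(0.3, 0.6),
            "elig_adults_step": int(rng.integers(2004, 2011)),
        })
    return pd.DataFrame(rows)


def _panel_state_params(config: SyntheticConfig) -> dict[str, dict]:
    """Staffing growth, labor-cost growth, grant and noise-scale draws."""
    rng = config.child_rng("state_params")
    attrs = _state_attributes(config).set_index("state")
    params: dict[str, dict] = {}
    for state in config.states:
        pop_m = attrs.loc[state, "pop_base"] / 1.0e6
        params[state] = {
            "pop_millions": pop_m,
            "fte_growth": {s: rng.uniform(*config.fte_growth_range) for s in SERVICES},
            "labor_growth": rng.uniform(*config.labor_growth_range),
            "grant_per_capita": rng.uniform(6.0, 10.0),
            "noise_scale": (float(np.exp(rng.normal(0.0, 0.3)))
                            if config.state_clustered_noise else 1.0),
        }
    return params


# --------------------------------------------------------------------------
# policy, population, CPI
# --------------------------------------------------------------------------

def generate_policy(config: SyntheticConfig) -> PolicyTables:
    """FMAP/EFMAP schedules, expansion status and CPI series."""
    rng = config.child_rng("policy")
    states = config.states
    qhp_states = states[: config.n_qhp_states]
    non_qhp = states[config.n_qhp_states:]
    n_expand = int(round(config.expansion_share * len(non_qhp)))
    expansion_states = set(qhp_states) | set(non_qhp[:n_expand])

    rows = []
    for state in states:
        fmap = rng.uniform(0.50, 0.76)
        expands = state in expansion_states
        for year in config.all_years:
            if year < 2014:
                efmap = fmap
            else:
                efmap = _EFMAP_SCHEDULE.get(year, _EFMAP_FLOOR)
            rows.append({
                "state": state,
                "year": year,
                "fmap": fmap,
                "efmap": max(efmap, fmap),
                "expansion_state": expands,
                "expansion_year": config.expansion_year_default if expands else np.nan,
                "qhp_expansion": state in qhp_states,
            })
    cpi = generate_cpi_series(config)
    return PolicyTables(pd.DataFrame(rows), cpi,
                        block_grant_inflation=config.block_grant_inflation,
                        dra_year=config.dra_year)


def generate_population(config: SyntheticConfig) -> PopulationTable:
    """Smooth per-state growth paths for the four population bands.

    Band populations grow exponentially at per-state, per-band rates over
    history plus projection years. Eligibility thresholds are piecewise
    constant, with the adult threshold jumping to 1.38 x FPL at the expansion
    year in expansion states, and all thresholds held at their last
    historical values through the projection years (status quo policy).
    """
    attrs = _state_attributes(config)
    policy = generate_policy(config)
    years = np.array(config.all_years)
    tau = years - config.history_years[0]
    rows = []
    for _, a in attrs.iterrows():
        state = a["state"]
        exp_year = policy.expansion_year(state)
        bands = {
            band: a["pop_base"] * _BAND_SHARES[band] * (1.0 + a[f"g_{band}"]) ** tau
            for band in POP_BANDS
        }
        for j, year in enumerate(years):
            elig_child = a["elig_child_1"] if year >= a["elig_child_step"] else a["elig_child_0"]
            elig_parents = a["elig_parents_1"] if year >= a["elig_parents_step"] else a["elig_parents_0"]
            elig_adults = a["elig_adults_1"] if year >= a["elig_adults_step"] else a["elig_adults_0"]
            if exp_year is not None and year >= exp_year:
                elig_adults = 1.38
            rows.append({
                "state": state,
                "year": int(year),
                **{f"pop_{band}": bands[band][j] for band in POP_BANDS},
                "elig_child": elig_child,
                "elig_parents": elig_parents,
                "elig_adults": elig_adults,
            })
    return PopulationTable(pd.DataFrame(rows))


def generate_cpi_series(config: SyntheticConfig) -> pd.DataFrame:
    """Historical CPI-U growth plus CPI-M = a + b*CPI-U + noise.

    CPI-M is only observed over the history years (as in real data, where
    future CPI-M must be predicted from projected CPI-U); projection years
    carry the CPI-U path only.
    """
    rng = config.child_rng("cpi")
    years = np.array(config.all_years)
    cpi_u = config.cpi_u_mean + rng.normal(0.0, config.cpi_u_sd, size=len(years))
    noise = rng.normal(0.0, config.noise_sd.get("cpi", 0.0), size=len(years))
    cpi_m = config.cpi_a + config.cpi_b * cpi_u + noise
    frame = pd.DataFrame({"year": years, "cpi_m": cpi_m, "cpi_u": cpi_u})
    frame.loc[frame["year"] > config.history_years[1], "cpi_m"] = np.nan
    return frame


# --------------------------------------------------------------------------
# panel
# --------------------------------------------------------------------------

def patient_design(pop: pd.DataFrame, payer: str,
                   marketplace_year: int = 2014) -> pd.DataFrame:
    """Regressor matrix of the patient model for one payer.

    Medicaid uses the five eligibility-scaled terms (no intercept); other
    payers use the raw population bands (eligibility set to 1), and
    private/self-pay add the 2014+ marketplace level dummy.
    """
    if payer == "medicaid":
        X = pd.DataFrame({
            "p1_18_x_echild": pop["pop_age1_18"] * pop["elig_child"],
            "p19_49f_x_eparents": pop["pop_age19_49_female"] * pop["elig_parents"],
            "p19_64_x_eadults": pop["pop_age19_64"] * pop["elig_adults"],
            "p65_x_eadults": pop["pop_age65_plus"] * pop["elig_adults"],
            "p19_64": pop["pop_age19_64"],
        })
    else:
        X = pd.DataFrame({
            "p1_18": pop["pop_age1_18"],
            "p19_49f": pop["pop_age19_49_female"],
            "p19_64": pop["pop_age19_64"],
            "p65": pop["pop_age65_plus"],
        })
        if payer in ("private", "self_pay"):
            X["marketplace"] = (pop["year"] >= marketplace_year).astype(float)
    X.index = pop.index
    return X


def _latent_patients(config: SyntheticConfig, pop: pd.DataFrame, payer: str) -> np.ndarray:
    X = patient_design(pop, payer)
    beta = np.asarray(config.true_patient_coeffs[payer], dtype=float)
    if payer in ("private", "self_pay"):
        beta = np.append(beta, config.marketplace_dummy[payer])
    return X.to_numpy() @ beta


def _revenue_pc_paths(
    config: SyntheticConfig, payer: str, years: np.ndarray,
    expansion_year: int | None, rng: np.random.Generator, noise_scale: float,
) -> tuple[np.ndarray, np.ndarray]:
    """(latent, realized) per-capita revenue; noise enters as innovations."""
    alpha = np.asarray(config.true_revenue_coeffs[payer], dtype=float)
    a0, a1, a2, a3, a4 = alpha
    if payer != "medicaid":
        a3 = 0.0  # expansion channel is Medicaid-specific
    tau = years - config.history_years[0]
    aca = ((years >= expansion_year).astype(float)
           if expansion_year is not None else np.zeros(len(years)))
    dra = (years > config.dra_year).astype(float)
    # the configured SD is denominated at the Medicaid per-capita level and
    # scaled to each payer's intercept, so small payers (e.g. self-pay) get
    # proportionally small innovations
    a0_ref = float(config.true_revenue_coeffs["medicaid"][0])
    sd = config.noise_sd["revenue_pc"] * noise_scale * (a0 / a0_ref)
    eps = rng.normal(0.0, 1.0, size=len(years)) * sd

    latent = np.empty(len(years))
    realized = np.empty(len(years))
    start = a0 / (1.0 - a1)
    latent[0] = start
    realized[0] = max(start + eps[0], 0.0)
    for j in range(1, len(years)):
        det = a0 + a2 * tau[j] + a3 * tau[j] * aca[j] + a4 * tau[j] * dra[j]
        latent[j] = det + a1 * latent[j - 1]
        realized[j] = max(det + a1 * realized[j - 1] + eps[j], 0.0)
    return latent, realized


def generate_panel(
    config: SyntheticConfig,
    population: PopulationTable,
    policy: PolicyTables,
) -> tuple[StatePanel, GroundTruth]:
    """Generate the observed panel and its ground truth.

    The panel covers the history years only (the projection years have no
    observed outcomes, as in the real UDS); the population table must cover
    them. Revenue per payer = patient count x per-capita revenue.
    """
    hist_years = np.arange(config.history_years[0], config.history_years[1] + 1)
    if not set(hist_years.tolist()) <= set(population.years):
        raise ValueError("population table does not cover the configured history years")

    params = _panel_state_params(config)
    rng_pat = config.child_rng("patients")
    rng_rev = config.child_rng("revenue")
    rng_fte = config.child_rng("fte")
    rng_fte_lv = config.child_rng("fte_levels")
    tau = hist_years - config.history_years[0]

    n_truncated = 0
    n_values = 0
    rows: list[dict] = []
    latent_rows: list[dict] = []
    pc_rows: list[dict] = []

    for state in config.states:
        p = params[state]
        noise_scale = p["noise_scale"]
        pop_s = population.for_state(state)
        pop_hist = pop_s[pop_s["year"].isin(hist_years)].reset_index(drop=True)
        exp_year = policy.expansion_year(state)

        patients, latent_patients = {}, {}
        beta_ref = float(np.sum(config.true_patient_coeffs["medicaid"]))
        for payer in PAYERS:
            lat = _latent_patients(config, pop_hist, payer)
            # scale the configured (Medicaid-level) SD to the payer's size
            payer_scale = float(np.sum(config.true_patient_coeffs[payer])) / beta_ref
            sd = config.noise_sd["patients"] * noise_scale * payer_scale
            noisy = lat + rng_pat.normal(0.0, 1.0, size=len(lat)) * sd
            n_values += len(noisy)
            n_truncated += int((noisy < 0).sum())
            patients[payer] = np.clip(noisy, 0.0, None)
            latent_patients[payer] = np.clip(lat, 0.0, None)

        revenue, latent_revenue = {}, {}
        for payer in PAYERS:
            lat_pc, real_pc = _revenue_pc_paths(
                config, payer, hist_years, exp_year, rng_rev, noise_scale)
            revenue[payer] = patients[payer] * real_pc
            latent_revenue[payer] = latent_patients[payer] * lat_pc
            pc_rows.extend(
                {"state": state, "year": int(y), "payer": payer, "revenue_pc": lat_pc[j]}
                for j, y in enumerate(hist_years)
            )

        # staffing trends carry seeded year-to-year hiring lumpiness; without
        # it the service-level FTE series are near-collinear exponentials and
        # the staff-mix cost coefficients are not separately identifiable.
        # The jitter is part of the observed FTE inputs (present even at zero
        # noise), so latent costs remain an exact function of the panel FTEs.
        fte = {
            svc: _FTE_BASE_PER_M[svc] * p["pop_millions"]
            * (1.0 + p["fte_growth"][svc]) ** tau
            * rng_fte_lv.uniform(0.85, 1.15, size=len(tau))
            for svc in SERVICES
        }

        growth = (1.0 + p["labor_growth"]) ** tau
        costs_latent, costs_realized = {}, {}
        for cat in COST_CATEGORIES:
            spec = config.true_fte_cost_coeffs[cat]
            if cat == "medical":
                Xc = np.column_stack([fte[s] for s in MEDICAL_SERVICES])
            else:
                Xc = fte[cat][:, None]
            lat = spec["beta0"] + (Xc @ np.asarray(spec["betas"], dtype=float)) * growth
            # the configured SD is denominated at the medical-category cost of
            # a 1M-resident state; scale to this category's and state's size so
            # small categories (e.g. substance use) are not drowned in noise
            betas = np.asarray(spec["betas"], dtype=float)
            svc_names = MEDICAL_SERVICES if cat == "medical" else [cat]
            base_cost = sum(b * _FTE_BASE_PER_M[s] for b, s in zip(betas, svc_names))
            ref_cost = sum(
                b * _FTE_BASE_PER_M[s]
                for b, s in zip(config.true_fte_cost_coeffs["medical"]["betas"],
                                MEDICAL_SERVICES))
            sd = (config.noise_sd["fte_cost"] * noise_scale
                  * (base_cost / ref_cost) * p["pop_millions"])
            noisy = lat + rng_fte.normal(0.0, 1.0, size=len(lat)) * sd
            n_values += len(noisy)
            n_truncated += int((noisy < 0).sum())
            costs_latent[cat] = np.clip(lat, 0.0, None)
            costs_realized[cat] = np.clip(noisy, 0.0, None)

        grant = p["grant_per_capita"] * p["pop_millions"] * 1.0e6 * 1.05 ** tau
        n_hc = np.maximum(np.round(8.0 * p["pop_millions"] * 1.04 ** tau), 1).astype(int)

        med_spec = config.true_fte_cost_coeffs["medical"]
        contrib = np.column_stack([
            np.asarray(med_spec["betas"], dtype=float)[k] * fte[s]
            for k, s in enumerate(MEDICAL_SERVICES)
        ])
        med_shares = contrib / contrib.sum(axis=1, keepdims=True)

        def _cost_columns(costs: dict) -> dict:
            # pooled medical cost allocated across staff columns by contribution
            out = {
                f"fte_cost_{s}": costs["medical"] * med_shares[:, k]
                for k, s in enumerate(MEDICAL_SERVICES)
            }
            out.update({f"fte_cost_{c}": costs[c] for c in COST_CATEGORIES if c != "medical"})
            return out

        for frame_rows, pats, revs, costs in (
            (rows, patients, revenue, costs_realized),
            (latent_rows, latent_patients, latent_revenue, costs_latent),
        ):
            cost_cols = _cost_columns(costs)
            frame_rows.extend(
                {
                    "state": state,
                    "year": int(year),
                    "n_health_centers": int(n_hc[j]),
                    **{f"patients_{py}": pats[py][j] for py in PAYERS},
                    "patients_total": sum(pats[py][j] for py in PAYERS),
                    **{f"revenue_{py}": revs[py][j] for py in PAYERS},
                    "revenue_total": sum(revs[py][j] for py in PAYERS),
                    "grant_revenue": grant[j],
                    **{f"fte_{s}": fte[s][j] for s in SERVICES},
                    **{k: v[j] for k, v in cost_cols.items()},
                }
                for j, year in enumerate(hist_years)
            )

    truncation_rate = n_truncated / max(n_values, 1)
    if truncation_rate > 0:
        logger.info("generator truncated %.3f%% of draws at zero", 100 * truncation_rate)

    panel = StatePanel(pd.DataFrame(rows))
    truth = GroundTruth(
        patient_coeffs={py: np.asarray(config.true_patient_coeffs[py], dtype=float)
                        for py in PAYERS},
        marketplace_dummy=dict(config.marketplace_dummy),
        revenue_coeffs=_truth_revenue_coeffs(config),
        fte_cost_coeffs={
            cat: {
                "beta0": float(config.true_fte_cost_coeffs[cat]["beta0"]),
                "betas": np.asarray(config.true_fte_cost_coeffs[cat]["betas"], dtype=float),
                "labor_growth": {s: params[s]["labor_growth"] for s in config.states},
            }
            for cat in COST_CATEGORIES
        },
        expansion_states={s: policy.expansion_year(s) for s in config.states},
        qhp_states=policy.qhp_states(),
        latent=pd.DataFrame(latent_rows),
        latent_revenue_pc=pd.DataFrame(pc_rows),
        truncation_rate=truncation_rate,
    )
    return panel, truth


def _truth_revenue_coeffs(config: SyntheticConfig) -> dict:
    out = {}
    for payer, alpha in config.true_revenue_coeffs.items():
        a = np.asarray(alpha, dtype=float).copy()
        if payer != "medicaid":
            a[3] = 0.0
        out[payer] = a
    return out


def generate_all(config: SyntheticConfig):
    """Convenience wrapper returning (panel, population, policy, ground_truth)."""
    population = generate_population(config)
    policy = generate_policy(config)
    panel, truth = generate_panel(config, population, policy)
    return panel, population, policy, truth
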