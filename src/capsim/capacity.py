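"""Translate revenue shortfalls into budget-neutral nonclinical FTE cuts.

Health-center leaders report they would absorb revenue shortages by cutting
nonbillable (enabling + administrative) staff before clinical staff. Under
that behavior, maintaining the baseline clinical budget while absorbing a
shortfall requires cutting the nonclinical budget by

    cut fraction = cumulative shortfall / cumulative nonclinical budget

over the 2020-2024 window. Cuts above 100% are reported as-is (some states'
shortfalls exceed their entire nonclinical budget) with a feasibility flag.

Two enrollment-behavior bounds bracket the impact: the **no-cuts** upper
bound absorbs the gross shortfall, while the **proportional-cuts** lower
bound disenrolls Medicaid patients in proportion to the revenue shortage, so
part of the loss is recovered as those patients move to self-pay (sliding
fee) revenue. A sensitivity sweep evaluates fixed disenrollment levels from
5% to 30% in 5-point increments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .baseline import BaselineProjection
from .core_data import CLINICAL_CATEGORIES

logger = logging.getLogger(__name__)

DEFAULT_SWEEP_LEVELS = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30)

ENROLLMENT_ASSUMPTIONS = ("no_cuts", "proportional_cuts")


@dataclass
class CostStructure:
    """State x year clinical/nonclinical budget split of the baseline.

    Columns: ``clinical_cost`` (budget allocated to medical, dental, mental
    health, substance use and other professional services), ``nonclinical_cost``
    (enabling + administrative), ``nonclinical_fte``.
    """

    df: pd.DataFrame


def cost_structure(baseline: BaselineProjection) -> CostStructure:
    b = baseline.df
    clinical = sum(
        b["revenue_total"] * b[f"alloc_share_{cat}"] for cat in CLINICAL_CATEGORIES
    )
    nonclinical = b["revenue_total"] * b["alloc_share_nonclinical"]
    return CostStructure(pd.DataFrame({
        "state": b["state"],
        "year": b["year"],
        "clinical_cost": clinical,
        "nonclinical_cost": nonclinical,
        "nonclinical_fte": b["baseline_fte_nonclinical"],
    }))


def compute_fte_cut(shortfall_abs: float, nonclinical_cost: float) -> tuple[float, bool]:
    """Nonclinical cut fraction absorbing a shortfall budget-neutrally.

    Returns ``(cut, feasible)``; the cut may exceed 1.0 (reported as-is) and
    is infinite when there is a shortfall but no nonclinical budget.
    """
    if shortfall_abs < 0:
        raise ValueError("shortfall must be floored at zero upstream")
    if nonclinical_cost <= 0:
        if shortfall_abs > 0:
            return float("inf"), False
        return 0.0, True
    cut = shortfall_abs / nonclinical_cost
    return cut, bool(cut <= 1.0)


def apply_enrollment_offset(
    shortfall_abs: float,
    medicaid_patients: float,
    medicaid_revenue: float,
    selfpay_pc_revenue: float,
    disenrollment_fraction: float,
) -> float:
    """Net shortfall after partial recovery from disenrolled patients.

    ``disenrollment_fraction`` of projected Medicaid patients move to the
    sliding-fee scale and generate the projected self-pay per-capita revenue;
    recovery is capped at the lost Medicaid revenue and the net shortfall is
    floored at zero.
    """
    if not 0.0 <= disenrollment_fraction <= 1.0:
        raise ValueError("disenrollment fraction must be within [0, 1]")
    disenrolled = disenrollment_fraction * medicaid_patients
    recovered = disenrolled * selfpay_pc_revenue
    lost = disenrollment_fraction * medicaid_revenue
    recovered = min(recovered, lost) if lost > 0 else 0.0
    return max(shortfall_abs - recovered, 0.0)


def _state_year_inputs(results: pd.DataFrame, baseline: BaselineProjection,
                       scenario: str) -> pd.DataFrame:
    rows = results[(results["scenario"] == scenario) & (results["group"] == "all")]
    merged = rows.merge(
        baseline.df[["state", "year", "patients_medicaid", "revenue_medicaid",
                     "revenue_pc_self_pay"]],
        on=["state", "year"], how="left")
    costs = cost_structure(baseline).df
    return merged.merge(costs, on=["state", "year"], how="left")


def compute_fte_impact(
    results: pd.DataFrame,
    baseline: BaselineProjection,
    enrollment_assumption: str = "no_cuts",
    disenrollment_level: float | None = None,
) -> pd.DataFrame:
    """Per state x scenario nonclinical cut fractions over the scenario window.

    Shortfalls and nonclinical budgets are accumulated across the projection
    years before taking the ratio. ``no_cuts`` uses the gross shortfall
    (upper bound); ``proportional_cuts`` disenrolls in proportion to each
    year's Medicaid revenue shortage (lower bound); a fixed
    ``disenrollment_level`` overrides the proportional rule for the
    sensitivity sweep.
    """
    if enrollment_assumption not in ENROLLMENT_ASSUMPTIONS:
        raise ValueError(f"unknown enrollment assumption {enrollment_assumption!r}")
    frames = []
    for scenario in sorted(results["scenario"].unique()):
        merged = _state_year_inputs(results, baseline, scenario)
        for state, grp in merged.groupby("state"):
            net_total = 0.0
            for _, r in grp.iterrows():
                gross = float(r["shortfall_abs"])
                if enrollment_assumption == "no_cuts":
                    net = gross
                else:
                    if disenrollment_level is not None:
                        frac = disenrollment_level
                    else:
                        rev = float(r["revenue_medicaid"])
                        frac = min(gross / rev, 1.0) if rev > 0 else 0.0
                    net = apply_enrollment_offset(
                        gross,
                        float(r["patients_medicaid"]),
                        float(r["revenue_medicaid"]),
                        float(r["revenue_pc_self_pay"]),
                        frac,
                    )
                net_total += net
            noncl_total = float(grp["nonclinical_cost"].sum())
            cut, feasible = compute_fte_cut(net_total, noncl_total)
            frames.append({
                "state": state,
                "scenario": scenario,
                "enrollment_assumption": enrollment_assumption,
                "disenrollment_level": (np.nan if disenrollment_level is None
                                        else disenrollment_level),
                "net_shortfall": net_total,
                "nonclinical_cost": noncl_total,
                "nonclinical_cut_pct": cut,
                "feasible": feasible,
            })
    return pd.DataFrame(frames)


def sensitivity_sweep(
    results: pd.DataFrame,
    baseline: BaselineProjection,
    levels=DEFAULT_SWEEP_LEVELS,
) -> pd.DataFrame:
    """FTE impacts across fixed disenrollment levels (default 5%..30% by 5pp).

    One row per state x scenario x level; with positive self-pay recovery the
    net shortfall (and hence the cut) is nonincreasing in the level.
    """
    levels = list(levels)
    if not levels:
        raise ValueError("levels must be non-empty")
    if any(not 0.0 <= lv <= 1.0 for lv in levels):
        raise ValueError("disenrollment levels must lie within [0, 1]")
    frames = [
        compute_fte_impact(results, baseline,
                           enrollment_assumption="proportional_cuts",
                           disenrollment_level=lv)
        for lv in levels
    ]
    return pd.concat(frames, ignore_index=True)
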