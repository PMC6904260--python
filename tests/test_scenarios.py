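import numpy as np
import pandas as pd
import pytest

from capsim.baseline import BaselineProjection
from capsim.core_data import PolicyTables
from capsim.scenarios import (
    compute_shortfall,
    enrollment_split,
    estimate_cpim_path,
    fixed_inflation_path,
    fmap_match_ratio,
    scenario_s0,
    scenario_s1_efmap_phaseout,
    scenario_s2_block_grant,
    scenario_s3_per_capita_cap,
    split_federal_state,
)

from conftest import make_shares_table

REL = 1e-8


def two_state_policy(years, fmap=0.5, efmap=0.9, expansion=True):
    rows = [
        {"state": s, "year": y, "fmap": fmap, "efmap": efmap,
         "expansion_state": expansion,
         "expansion_year": 2014 if expansion else np.nan,
         "qhp_expansion": False}
        for s in ("AA", "BB") for y in years
    ]
    cpi = pd.DataFrame({"year": list(years), "cpi_m": 0.03, "cpi_u": 0.02})
    return PolicyTables(pd.DataFrame(rows), cpi)


# ---------------------------------------------------------------------------
# match arithmetic
# ---------------------------------------------------------------------------

def test_split_federal_state_oracle():
    federal, state = split_federal_state(100.0, 0.5)
    assert federal == 50.0 and state == 50.0
    federal, state = split_federal_state(200.0, 0.75)
    assert federal == pytest.approx(150.0) and state == pytest.approx(50.0)


def test_fmap_match_ratio_printed_values():
    assert round(fmap_match_ratio(0.7565), 2) == 3.11
    assert fmap_match_ratio(0.5) == 1.0


# ---------------------------------------------------------------------------
# inflation paths
# ---------------------------------------------------------------------------

def test_fixed_inflation_path_oracle():
    path = fixed_inflation_path(range(2016, 2025), rate=0.023, base_year=2016)
    assert path.multiplier(2016) == 1.0
    assert path.multiplier(2024) == pytest.approx(1.023 ** 8, rel=1e-12)
    assert path.annual_rate(2020) == pytest.approx(0.023, rel=1e-12)


def test_cpim_path_trivial_constant():
    years = list(range(2000, 2025))
    cpi = pd.DataFrame({"year": years, "cpi_m": 0.03, "cpi_u": 0.02})
    cpi.loc[cpi["year"] > 2016, "cpi_m"] = np.nan
    path = estimate_cpim_path(cpi, base_year=2016, through=2024)
    # constant CPI-U implies predicted CPI-M growth is the observed constant
    assert path.multiplier(2024) == pytest.approx(1.03 ** 8, rel=1e-9)


def test_cpim_path_affine_recovery():
    rng = np.random.default_rng(3)
    years = np.arange(2000, 2025)
    cpi_u = 0.02 + rng.normal(0, 0.004, len(years))
    cpi_m = 0.012 + 0.9 * cpi_u  # exact affine relation, no noise
    frame = pd.DataFrame({"year": years, "cpi_m": cpi_m, "cpi_u": cpi_u})
    frame.loc[frame["year"] > 2016, "cpi_m"] = np.nan
    path = estimate_cpim_path(frame, base_year=2016, through=2024)
    expected = np.prod(1.0 + (0.012 + 0.9 * cpi_u[(years > 2016) & (years <= 2024)]))
    assert path.multiplier(2024) == pytest.approx(expected, rel=1e-9)


def test_cpim_path_insufficient_history():
    years = list(range(2014, 2025))
    cpi = pd.DataFrame({"year": years, "cpi_m": 0.03, "cpi_u": 0.02})
    cpi.loc[cpi["year"] > 2016, "cpi_m"] = np.nan
    with pytest.raises(ValueError):
        estimate_cpim_path(cpi, base_year=2016, through=2024, min_overlap=10)


# ---------------------------------------------------------------------------
# enrollment split
# ---------------------------------------------------------------------------

def test_enrollment_split_nonexpansion_zero(default_data):
    panel, pop, policy, truth = default_data
    from capsim.baseline import fit_patient_model
    models = fit_patient_model(panel, pop, "medicaid")
    split = enrollment_split(models, pop, policy, list(range(2020, 2025)))
    for state, exp_year in truth.expansion_states.items():
        rows = split[split["state"] == state]
        if exp_year is None:
            assert np.allclose(rows["enrollees_expansion"], 0.0)
        else:
            assert (rows["enrollees_expansion"] > 0).all()
    assert ((split["expansion_ratio"] >= 0) & (split["expansion_ratio"] <= 1)).all()
    assert np.allclose(split["enrollees_traditional"] + split["enrollees_expansion"],
                       split["enrollees_total"], rtol=1e-12)


# ---------------------------------------------------------------------------
# S1 EFMAP phase-out
# ---------------------------------------------------------------------------

def test_s1_reduction_hand_oracle():
    # (90% - 50%) x $5,000 per enrollee x 1,000 enrollees = $2M
    shares = make_shares_table([
        {"state": "AA", "year": 2020, "group": "traditional",
         "enrollees": 2000.0, "medicaid_revenue": 2000 * 5000.0, "match_rate": 0.5},
        {"state": "AA", "year": 2020, "group": "expansion",
         "enrollees": 1000.0, "medicaid_revenue": 1000 * 5000.0, "match_rate": 0.9},
    ])
    policy = two_state_policy([2016, 2020], fmap=0.5, efmap=0.9)
    out = scenario_s1_efmap_phaseout(shares, policy)
    exp = out[out["group"] == "expansion"].iloc[0]
    assert exp["shortfall_abs"] == pytest.approx(2.0e6, rel=REL)
    trad = out[out["group"] == "traditional"].iloc[0]
    assert trad["shortfall_abs"] == 0.0


def test_s1_nonexpansion_states_zero(default_data):
    # states that never expanded have zero expansion enrollees, so S1 leaves
    # every row untouched
    shares = make_shares_table([
        {"state": "AA", "year": 2020, "group": "traditional",
         "enrollees": 1000.0, "medicaid_revenue": 5.0e6, "match_rate": 0.6},
        {"state": "AA", "year": 2020, "group": "expansion",
         "enrollees": 0.0, "medicaid_revenue": 0.0, "match_rate": 0.9},
    ])
    policy = two_state_policy([2016, 2020], expansion=False)
    out = scenario_s1_efmap_phaseout(shares, policy)
    assert np.allclose(out["shortfall_abs"], 0.0)


def test_s1_null_when_efmap_equals_fmap():
    shares = make_shares_table([
        {"state": "AA", "year": 2020, "group": "expansion",
         "enrollees": 1000.0, "medicaid_revenue": 5.0e6, "match_rate": 0.6},
    ])
    policy = two_state_policy([2016, 2020], fmap=0.6, efmap=0.6)
    out = scenario_s1_efmap_phaseout(shares, policy)
    assert np.allclose(out["shortfall_abs"], 0.0, atol=1e-12)


def test_s1_rejects_inconsistent_expansion_flags():
    shares = make_shares_table([
        {"state": "AA", "year": 2020, "group": "expansion",
         "enrollees": 10.0, "medicaid_revenue": 1.0e4, "match_rate": 0.9},
    ])
    policy = two_state_policy([2016, 2020], expansion=False)
    with pytest.raises(ValueError, match="nonexpansion state"):
        scenario_s1_efmap_phaseout(shares, policy)


# ---------------------------------------------------------------------------
# S2 block grant
# ---------------------------------------------------------------------------

def _s2_shares(years, revenue_by_year, enrollees=1000.0, match=0.6):
    return make_shares_table([
        {"state": "AA", "year": y, "group": g,
         "enrollees": enrollees if g == "traditional" else 0.0,
         "medicaid_revenue": revenue_by_year[y] if g == "traditional" else 0.0,
         "match_rate": match if g == "traditional" else 0.9}
        for y in years for g in ("traditional", "expansion")
    ])


def test_s2_exponentiation_oracle():
    # $100M base grows to ~$119.95M by 2024 at 2.3%/yr
    years = [2024]
    shares = _s2_shares(years, {2024: 1.0e9})
    base = pd.Series({"AA": 100.0e6})
    path = fixed_inflation_path(range(2016, 2025))
    out = scenario_s2_block_grant(shares, base, path)
    trad = out[out["group"] == "traditional"].iloc[0]
    assert trad["scenario_federal"] == pytest.approx(100.0e6 * 1.023 ** 8, rel=1e-12)
    assert round(trad["scenario_federal"] / 1e6, 2) == 119.95


def test_s2_enrollment_invariance():
    years = [2020, 2024]
    rev = {2020: 5.0e8, 2024: 6.0e8}
    base = pd.Series({"AA": 1.0e8})
    path = fixed_inflation_path(range(2016, 2025))
    out1 = scenario_s2_block_grant(_s2_shares(years, rev, enrollees=1000.0), base, path)
    out2 = scenario_s2_block_grant(_s2_shares(years, rev, enrollees=9999.0), base, path)
    assert np.allclose(out1["scenario_federal"], out2["scenario_federal"], rtol=1e-12)


def test_s2_growth_matched_limit_zero_shortfall():
    # baseline federal growing at exactly 2.3%/yr from the 2016 base ->
    # zero shortfall in every year
    match = 0.6
    rev0 = 1.0e8
    years = list(range(2020, 2025))
    rev = {y: rev0 * 1.023 ** (y - 2016) for y in years}
    shares = _s2_shares(years, rev, match=match)
    base = pd.Series({"AA": match * rev0})
    path = fixed_inflation_path(range(2016, 2025))
    out = scenario_s2_block_grant(shares, base, path)
    rel = out["shortfall_abs"] / np.maximum(out["baseline_federal"], 1.0)
    assert (rel.abs() <= REL).all()


def test_s2_without_phaseout_nests_s0():
    years = [2020, 2021]
    match = 0.6
    rev0 = 1.0e8
    rev = {y: rev0 * 1.023 ** (y - 2016) for y in years}
    rows = []
    for y in years:
        rows.append({"state": "AA", "year": y, "group": "traditional",
                     "enrollees": 1000.0, "medicaid_revenue": rev[y],
                     "match_rate": match})
        rows.append({"state": "AA", "year": y, "group": "expansion",
                     "enrollees": 500.0, "medicaid_revenue": 0.5 * rev[y],
                     "match_rate": 0.9})
    shares = make_shares_table(rows)
    base = pd.Series({"AA": match * rev0})
    path = fixed_inflation_path(range(2016, 2025))
    out = scenario_s2_block_grant(shares, base, path, apply_expansion_phaseout=False)
    s0 = scenario_s0(shares)
    assert np.allclose(out["scenario_federal"], s0["scenario_federal"], rtol=REL)


def test_s2_missing_base_state_raises():
    shares = _s2_shares([2020], {2020: 1.0e8})
    path = fixed_inflation_path(range(2016, 2025))
    with pytest.raises(KeyError, match="AA"):
        scenario_s2_block_grant(shares, pd.Series(dtype=float), path)


# ---------------------------------------------------------------------------
# S3 per-capita cap
# ---------------------------------------------------------------------------

def _s3_inputs(pc_by_state_year, enrollees_by_state_year, match=0.6,
               scenario_years=(2020, 2021)):
    rows, pc_rows = [], []
    states = sorted(pc_by_state_year)
    years = sorted({y for s in states for y in pc_by_state_year[s]})
    for s in states:
        for y in years:
            enr = enrollees_by_state_year[s][y]
            pc = pc_by_state_year[s][y]
            pc_rows.append({"state": s, "year": y, "enrollees": enr,
                            "pc_expenditure": pc, "medicaid_revenue": enr * pc})
            if y in scenario_years:
                rows.append({"state": s, "year": y, "group": "traditional",
                             "enrollees": enr, "medicaid_revenue": enr * pc,
                             "match_rate": match})
                rows.append({"state": s, "year": y, "group": "expansion",
                             "enrollees": 0.0, "medicaid_revenue": 0.0,
                             "match_rate": 0.9})
    return make_shares_table(rows), pd.DataFrame(pc_rows)


def test_s3_cap_composition_oracle():
    # cap_2021 = 4000 x 1.023 x (1 + 0.10) = 4501.20
    pc = {
        "AA": {2019: 1000.0, 2020: 1100.0, 2021: 1100.0},
        "BB": {2019: 1000.0, 2020: 900.0, 2021: 900.0},
    }
    enr = {s: {y: 1000.0 for y in (2019, 2020, 2021)} for s in ("AA", "BB")}
    shares, pc_frame = _s3_inputs(pc, enr)
    base = pd.Series({"AA": 4000.0, "BB": 4000.0})
    path = fixed_inflation_path(range(2020, 2025), base_year=2020)
    out = scenario_s3_per_capita_cap(shares, base, path, pc_frame, start_year=2020)
    aa = out[(out["state"] == "AA") & (out["group"] == "traditional")]
    cap_2020 = aa[aa["year"] == 2020]["scenario_federal"].iloc[0] / 1000.0
    cap_2021 = aa[aa["year"] == 2021]["scenario_federal"].iloc[0] / 1000.0
    assert cap_2020 == pytest.approx(4000.0, rel=1e-12)  # zero 2019 deviance
    assert round(cap_2021, 2) == 4501.20


def test_s3_rebase_mode_applies_deviance_once():
    pc = {
        "AA": {2019: 1100.0, 2020: 1100.0, 2021: 1100.0},
        "BB": {2019: 900.0, 2020: 900.0, 2021: 900.0},
    }
    enr = {s: {y: 1000.0 for y in (2019, 2020, 2021)} for s in ("AA", "BB")}
    shares, pc_frame = _s3_inputs(pc, enr)
    base = pd.Series({"AA": 4000.0, "BB": 4000.0})
    path = fixed_inflation_path(range(2020, 2025), base_year=2020)
    out = scenario_s3_per_capita_cap(shares, base, path, pc_frame,
                                     start_year=2020, deviance_mode="rebase_2020")
    aa = out[(out["state"] == "AA") & (out["group"] == "traditional")]
    cap_2020 = aa[aa["year"] == 2020]["scenario_federal"].iloc[0] / 1000.0
    cap_2021 = aa[aa["year"] == 2021]["scenario_federal"].iloc[0] / 1000.0
    assert cap_2020 == pytest.approx(4000.0 * 1.1, rel=1e-12)
    assert cap_2021 == pytest.approx(4000.0 * 1.1 * 1.023, rel=1e-12)


def test_s3_homogeneous_degree_one_in_enrollment():
    pc = {
        "AA": {2019: 1000.0, 2020: 1050.0, 2021: 1050.0},
        "BB": {2019: 1000.0, 2020: 950.0, 2021: 950.0},
    }
    enr = {s: {y: 1000.0 for y in (2019, 2020, 2021)} for s in ("AA", "BB")}
    half = {s: {y: 500.0 for y in (2019, 2020, 2021)} for s in ("AA", "BB")}
    base = pd.Series({"AA": 600.0, "BB": 600.0})
    path = fixed_inflation_path(range(2020, 2025), base_year=2020)
    shares_full, pc_frame = _s3_inputs(pc, enr)
    shares_half, _ = _s3_inputs(pc, half)
    out_full = scenario_s3_per_capita_cap(shares_full, base, path, pc_frame)
    out_half = scenario_s3_per_capita_cap(shares_half, base, path, pc_frame)
    assert np.allclose(out_half["scenario_federal"],
                       0.5 * out_full["scenario_federal"], rtol=REL)


def test_s3_growth_matched_limit_zero_shortfall():
    # identical states (zero deviance), per-capita expenditure growing at
    # exactly 2.3%/yr, base cap = base-year federal per enrollee ->
    # the cap tracks baseline federal exactly
    match = 0.6
    years = list(range(2019, 2025))
    pc = {s: {y: 1000.0 * 1.023 ** (y - 2016) for y in years} for s in ("AA", "BB")}
    enr = {s: {y: 1000.0 for y in years} for s in ("AA", "BB")}
    shares, pc_frame = _s3_inputs(pc, enr, match=match,
                                  scenario_years=tuple(range(2020, 2025)))
    base = pd.Series({s: match * 1000.0 for s in ("AA", "BB")})
    path = fixed_inflation_path(range(2016, 2025), base_year=2016)
    out = scenario_s3_per_capita_cap(shares, base, path, pc_frame, start_year=2020)
    trad = out[out["group"] == "traditional"]
    rel = (trad["baseline_federal"] - trad["scenario_federal"]).abs() / trad["baseline_federal"]
    assert (rel <= REL).all()


def test_s3_zero_national_average_raises():
    pc = {"AA": {2019: 0.0, 2020: 0.0}}
    enr = {"AA": {2019: 1000.0, 2020: 1000.0}}
    shares, pc_frame = _s3_inputs(pc, enr, scenario_years=(2020,))
    base = pd.Series({"AA": 600.0})
    path = fixed_inflation_path(range(2020, 2025), base_year=2020)
    with pytest.raises(ValueError, match="national average"):
        scenario_s3_per_capita_cap(shares, base, path, pc_frame)


# ---------------------------------------------------------------------------
# shortfall summary
# ---------------------------------------------------------------------------

def test_compute_shortfall_group_additivity_and_pct():
    shares = make_shares_table([
        {"state": "AA", "year": 2020, "group": "traditional",
         "enrollees": 1000.0, "medicaid_revenue": 4.0e6, "match_rate": 0.5},
        {"state": "AA", "year": 2020, "group": "expansion",
         "enrollees": 500.0, "medicaid_revenue": 2.0e6, "match_rate": 0.9},
    ])
    policy = two_state_policy([2016, 2020], fmap=0.5, efmap=0.9)
    results = scenario_s1_efmap_phaseout(shares, policy)
    baseline = BaselineProjection(
        pd.DataFrame({"state": ["AA"], "year": [2020], "revenue_total": [10.0e6]}),
        base_year=2016)
    out = compute_shortfall(baseline, results)
    groups = out[out["group"] != "all"]
    allrow = out[out["group"] == "all"].iloc[0]
    assert allrow["shortfall_abs"] == pytest.approx(groups["shortfall_abs"].sum(), rel=1e-12)
    # expansion reduction: (0.9 - 0.5) x 4000 pc x 500 = 0.8e6
    exp = groups[groups["group"] == "expansion"].iloc[0]
    assert exp["shortfall_abs"] == pytest.approx(0.8e6, rel=1e-12)
    assert exp["shortfall_pct"] == pytest.approx(0.8e6 / 2.0e6, rel=1e-12)
    assert allrow["shortfall_pct"] == pytest.approx(0.8e6 / 10.0e6, rel=1e-12)


def test_compute_shortfall_zero_denominator_flagged():
    shares = make_shares_table([
        {"state": "AA", "year": 2020, "group": "expansion",
         "enrollees": 0.0, "medicaid_revenue": 0.0, "match_rate": 0.9},
    ])
    results = scenario_s0(shares)
    baseline = BaselineProjection(
        pd.DataFrame({"state": ["AA"], "year": [2020], "revenue_total": [0.0]}),
        base_year=2016)
    out = compute_shortfall(baseline, results)
    assert out["pct_undefined"].all()
    assert out["shortfall_pct"].isna().all()
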