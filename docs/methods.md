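# Methods

This document records the modeling assumptions, the synthetic data
generator's calibration, the numerical choices, and the resolutions of
design questions the model statement leaves open.

## 1. Data model

The analysis consumes four tables (see `capsim.core_data` for schemas):

* **panel** — state × year health-center aggregates over the history years
  (2000–2016 by default): patient counts and revenues by payer (medicaid,
  medicare, private, self_pay, other_public), grant revenue, and FTE counts
  and personnel costs by service (physicians, NP/PA/CNM, dental, mental
  health, substance use, other professional, non-clinical). Validation checks
  non-negativity, payer-sum consistency, and year contiguity.
* **population** — state × year census bands P(1–18), P(19–49, female),
  P(19–64), P(65+) and Medicaid income-eligibility thresholds (× FPL) for
  children, parents, and childless adults, covering history and projection
  years.
* **policy** — state × year FMAP and EFMAP, expansion status and year, and a
  flag for states that expanded via marketplace (QHP) premium assistance;
  those states are excluded from analysis because their expansion enrollees
  do not appear in health-center Medicaid revenue the same way.
* **cpi** — CPI-U growth for all years and CPI-M (medical care) growth for
  history years only.

## 2. Estimators

### Eq (1): patient model

Per state and payer, OLS of patient counts on the design in
`synthetic.patient_design`. Medicaid uses five eligibility-scaled terms and
no intercept; identification of the per-state coefficients comes from the
within-state time variation in eligibility thresholds (legislated step
changes plus the 1.38 × FPL expansion jump). Other payers use raw bands;
private and self-pay add a 2014+ marketplace level dummy. Rank deficiency
raises an error naming the collinear regressors rather than silently
dropping them.

### Eq (2): per-capita revenue recursion

Per state and payer, OLS of `R_t` on `(1, R_{t-1}, t, t·ACA_t, t·DRA_t)`,
`t = year − 2000`. The default (`smooth=True`) applies a centered 3-year
moving average to the dependent series. Because the centered mean of a
series obeying the recursion obeys the same recursion with the interaction
regressors replaced by their own centered means, those regressors are
smoothed with the identical filter and rows whose value or lag falls in a
partial endpoint window are dropped; this makes the smoothed fit exact on
noiseless data. The ACA term is dropped (with a warning) in states where it
is identically zero; a fitted `|a1| ≥ 1` sets an explosive-forecast flag.
Forecasts iterate the recursion from the last observed (optionally smoothed)
per-capita value, clamping at zero.

### Eq (3): FTE cost model

Per state and category, `C_t = g0 + (F_t·g)·(1+r)^t` is fitted by profiling
`r`: a 0.005-step grid on [−0.02, 0.10] followed by bounded scalar
minimization (`xatol = 1e-12`) around the best grid point, with `g` obtained
by least squares at each candidate `r`. Confidence intervals use the joint
nonlinear-least-squares delta method with Jacobian
`[1, F·(1+r)^t, (F·g)·t·(1+r)^(t−1)]`. Two numerical points matter here:

* The profile likelihood is nearly flat in `r`, so `J'J` has condition
  numbers up to ~1e18. A pseudo-inverse would *truncate* the flat direction
  and shrink the variance exactly where it should be large; instead the
  matrix is equilibrated (symmetrically scaled by its diagonal) and inverted
  exactly, which yields the appropriately wide intervals.
* Conditioning on the profiled `r` (plain OLS intervals at `r = r̂`)
  understates the g's uncertainty badly (observed coverage ~20–50%); the
  joint delta-method intervals achieve ~95%.

When `labor_growth` is supplied externally the model is linear and
conditional OLS inference is exact.

### Baseline projection (S0)

Patients and per-capita revenues are projected per payer for 2017–2024;
revenue = patients × per-capita revenue, plus grant revenue held at its last
observed level. Category budgets allocate total revenue by base-year cost
shares; projected per-FTE costs from Eq (3) (at base-year staff mix) convert
budgets into baseline FTE counts.

## 3. Scenario engine

Projected Medicaid enrollment is split into traditional and expansion
groups: expansion enrollees are the excess of the Eq (1) projection under
actual thresholds over a counterfactual projection with the adult threshold
frozen at its last pre-expansion level, floored at zero. Projected Medicaid
revenue is split between the groups in proportion to enrollees, and matched
at the state's 2016 FMAP (traditional) or the year's EFMAP (expansion).

* **S1** reduces the expansion group's federal contribution by
  `(EFMAP₂₀₁₆ − FMAP₂₀₁₆) × per-capita expenditure × expansion enrollees`.
  It is identically zero for nonexpansion states.
* **S2** fixes the traditional federal contribution at its observed 2016
  level grown by the inflation path (fixed 2.3%/yr, or a CPI-M path
  estimated from a CPI-M ~ CPI-U regression on the overlap years and
  accumulated over projected CPI-U). It is invariant to enrollment. The
  expansion group's match is phased out (scenario federal 0); a flag
  disables the phase-out, in which case S2 nests S0 when baseline growth
  matches the path.
* **S3** sets a per-enrollee cap: the 2015–16 mean traditional per-capita
  federal contribution, inflated to 2020 and adjusted by the state's percent
  deviance of projected per-capita expenditure from the enrollee-weighted
  national average in the prior year. With `deviance_mode="annual"` (default)
  the deviance factor composes every year (a dynamic forecast); with
  `"rebase_2020"` it applies once and the cap then grows by inflation only.
  The scenario contribution is the cap times **total** projected enrollees,
  making S3 homogeneous of degree one in enrollment.

Shortfall = baseline federal − scenario federal, floored at zero by default
(surpluses are reported separately so the floor loses no information).
Percentages use group Medicaid revenue for group rows and total baseline
revenue (all payers + grants) for the aggregated `all` rows; zero
denominators yield NaN with a `pct_undefined` flag.

In both growth-matched limits — baseline federal growing at exactly the
grant inflation (S2), and identical states with per-capita expenditure
growing at exactly the cap inflation (S3) — the scenarios reproduce the
baseline to rounding error; these are enforced as invariants in the tests.

## 4. Capacity impact

Per state × scenario, the cut share is the cumulative 2020–2024 net
shortfall over the cumulative non-clinical budget (base-year cost share ×
projected total revenue). Cuts above 100% are reported as-is with
`feasible=False`; a shortfall against a zero budget reports `inf`. The
**no_cuts** upper bound uses the gross shortfall; the
**proportional_cuts** lower bound disenrolls Medicaid patients in proportion
to each year's revenue shortage (capped at 100%), recovering the projected
self-pay per-capita revenue per disenrolled patient, capped at the lost
Medicaid revenue and floored at zero net shortfall. The sensitivity sweep
fixes disenrollment at 5%…30% in 5-point steps; because recovery is
nondecreasing in the level, the cut is monotonically nonincreasing across
the sweep.

## 5. Synthetic data generator

The generator (`capsim.synthetic`) draws an eight-state population by
default: two QHP-expansion states (excluded from analysis), three
conventional 2014 expanders, three never-expanders. All randomness flows
through named child streams of one master seed (`population`, `policy`,
`state_params`, `patients`, `revenue`, `fte`, `cpi`, `fte_levels`), so any
subset of tables is reproducible independently.

Key calibration choices, in units:

* Population bands: base 1–8M persons, band growth 0.2–1.5%/yr; eligibility
  thresholds 0.2–2.6 × FPL with one legislated step per group per state
  (these steps identify Eq (1)).
* Patient coefficients: Medicaid (0.012, 0.020, 0.010, 0.008, 0.004);
  marketplace dummy +3,000 private / −4,000 self-pay persons from 2014.
* Revenue recursions (per-capita USD): e.g. Medicaid
  (a0 400, a1 0.5, trend 4, ACA 3, DRA 2); noise enters as AR *innovations*
  (the realized lag feeds forward), so the unsmoothed regression is exactly
  correctly specified.
* FTE costs: fixed costs 0.2–2.0 ×10⁵ USD, 0.7–2.4 ×10⁵ USD per FTE, labor
  growth 1–5%/yr per state. Per-year staffing levels carry a ±15% uniform
  jitter: without it the staff-mix series are near-collinear smooth
  exponentials and the medical-category g's are unidentified. The jitter is
  part of the observed inputs (present at zero noise), so noiseless recovery
  stays exact.
* Noise scales: the configured SDs are Medicaid-level (patients 800 persons,
  revenue 8 USD per capita, FTE cost 1e5 USD, CPI 0.002) and are rescaled to
  each payer's/category's/state's magnitude (coefficient-sum ratios for
  patients, intercept ratios for revenue, base-cost × state-size ratios for
  FTE costs), so every series has a comparable signal-to-noise ratio.
* FMAP ~ U(0.50, 0.76) per state; EFMAP = max(schedule, FMAP) with the
  schedule 1.00 (2014–16), 0.95, 0.94, 0.93, then 0.90 from 2020; EFMAP =
  FMAP before 2014. CPI-M = 0.012 + 0.9 × CPI-U + noise, observed only over
  history years.

Negative draws are truncated at zero; the realized truncation rate is
reported in the ground truth (≈0.1% at default noise).

## 6. Validation

* **Exact recovery**: with all noise SDs zero, Eqs (1)–(3) recover the
  generating coefficients to ≤ 1e-6 relative error (observed ≤ 5e-7; the
  Eq (3) error is dominated by the profiled `r` tolerance).
* **Coverage**: over 200 default-noise seeds the 95% CIs cover the truth at
  95.0% (Eq 1), 91.8% (Eq 2, unsmoothed fit), and 95.2% (Eq 3). Coverage is
  assessed on the *unsmoothed* Eq (2) estimator because the smoothing
  filter's overlapping-window error is correlated with the smoothed lag
  regressor, so the smoothed fit's nominal OLS intervals undercover by
  construction (~77% observed) even though its point estimates are exact on
  noiseless data.
* **Oracle equivalence**: the vectorized projections and scenario
  contributions equal naive scalar year-by-year reimplementations to 1e-10
  relative on five-state fixtures.
* **Determinism**: identical configs produce byte-identical artifacts;
  reruns from exported CSVs match in-memory runs (CSV reads use
  `float_precision="round_trip"`).

## 7. Open design questions and resolutions

* **Projection seed**: the Eq (2) recursion is seeded from the last *raw*
  observed per-capita value by default (`smooth_seed=True` uses the smoothed
  one); raw is the observable quantity and avoids leaking the endpoint
  filter into the forecast.
* **S3 cap base applies to total enrollment**: the cap is derived from
  traditional per-capita federal spending but multiplies total projected
  enrollees, reflecting that a statutory cap would cover the whole caseload.
* **Deviance composition**: `annual` (composing) is the default because the
  cap is a dynamic forecast; `rebase_2020` is available for a one-time
  adjustment.
* **ACA trend is Medicaid-only**: the `t·ACA` interaction enters only the
  Medicaid revenue recursion; other payers carry the marketplace effect in
  the patient model's 2014+ level dummy instead.
* **Shortfall floors**: scenario gains (negative shortfalls) are floored at
  zero for the headline numbers but preserved in `surplus_abs`, and
  `floor_at_zero=False` disables the floor entirely.
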