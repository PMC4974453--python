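# Methods

`wardflow` models the number of patients discharged from a single open
hospital ward on the next calendar day, using only routinely collected
administrative data (admission/discharge timestamps and coarse categorical
patient attributes) — no real-time clinical information. This note records
the modelling choices, the defaults and why, and what the synthetic data
generator does and does not emulate.

## The forecasting problem

Let `y_t` be the number of ward discharges on day `t`. Each forecaster
produces a real-valued one-step-ahead estimate of `y_d` using only data with
timestamps strictly before day `d` (plus the calendar identity of `d`
itself, which is known in advance). Evaluation is rolling and
time-separated: models are fit on an initial block, then walked day by day
across a held-out tail, scored with MFE, MAE, RMSE and sMAPE, an MAE
improvement over a naive reference, and a per-day-of-week MAE breakdown.

Forecasts are left unrounded. Error metrics on count data are perfectly
well defined for real forecasts, and rounding only discards information;
the CLI offers `--round` for operational use.

## Synthetic ward-flow generator

No hospital extract ships with the package, so a seeded simulator
(`wardflow.synthetic`) generates the three raw tables with the structure
the analysis assumes:

- **Admissions** are a nonhomogeneous Poisson process: rate =
  `base_admission_rate` (default 8.6/day) × a Mon–Sun multiplier × an
  annual sinusoid of amplitude `monthly_amplitude` (default 0.15). A
  Poisson count is the simplest process matching a target mean with
  controllable seasonality.
- **Discharge** is *not* an i.i.d. length-of-stay draw. Each patient faces
  a daily discharge hazard from the day after entry: baseline
  `base_discharge_hazard` (0.232) × a weekday multiplier (default
  Mon–Sun: 1.10, 1.15, 1.20, 1.30, 1.60, 0.40, 0.30). This couples the
  realized LOS to the discharge weekday and is what produces the "weekend
  effect" — a Friday discharge peak and a weekend trough — which is the
  central structure the forecasters must exploit. The baseline hazard was
  chosen by Monte-Carlo search so that realized LOS has median 3 days and
  mean ≈ 4.26 under the default weekday multipliers; a 60-day cap keeps
  the law proper.
- **Attributes** (admission type ×5, referral source ×49, patient class
  ×21, age band ×8, wards-visited band ×4, gender) are drawn from
  configurable probability vectors over synthetic vocabularies
  ("REF_01".."REF_49" etc.); the defaults decay geometrically so some
  categories are common and many are rare, as in real administrative data.
- Timestamps are hour-resolution uniform within the day; the analysis uses
  calendar dates only.

**What the defaults reproduce:** mean discharges/day ≈ 8.7 (median 8), LOS
median 3 / mean ≈ 4.26, a pronounced Friday peak and weekend trough, a mild
annual cycle, no long-term trend. **What they cannot reproduce:** the
published cohort's mean occupancy of ≈ 31 is inconsistent with its own
admission rate and mean LOS (by Little's law, 8.6 × 4.26 ≈ 36.6), so the
simulator honours the rate and LOS targets and runs at mean occupancy ≈ 36.
The simulator also has no capacity cap, no bed-level assignment, no
inter-ward transfer network, and its attributes are independent of LOS —
so a passing ordering test shows the pipeline recovers *planted* structure,
not that any model would win on real hospital data.

## Daily series and conventions

A stay occupies the half-open interval `[entry_date, exit_date)`:
occupancy is an end-of-day census, a discharge belongs to the calendar date
of ward exit, and a bed is never double-counted on turnover day. Under
these conventions the conservation identity `o_t = o_{t-1} + a_t − y_t`
holds exactly, and `|roster(d)| = o_d` for every day. Same-day
admit-and-discharge would count as LOS 1 (there is no zero band); the
simulator never emits it. Missing categorical values are mapped to an
explicit `UNKNOWN` level rather than dropped, because patient-level
predictors are roster counts and must not silently shrink; an `UNKNOWN`
patient is counted in occupancy but in none of that attribute's category
columns, so the partition identities (each count family sums to
previous-day occupancy) are exact only when no values are missing — always
true for simulated data.

## The 108 predictors

For target day `d` (information cutoff: end of `d−1`):

- **Ward level (20):** day-of-week (Mon=1..Sun=7) and month of `d`;
  a loess trend (below); admission lags `a_{d−1..d−7}`; discharge lags
  `y_{d−1..d−7}`; `y_{d−14}`; `y_{d−21}`; previous-day occupancy `o_{d−1}`.
- **Patient level (88), over the roster at end of `d−1`:** counts by
  admission type (5), referral (49), patient class (21), age band (8),
  wards-visited band (4), plus the mean elapsed LOS of current patients.

The weekly discharge/admission history enters as seven individual lags
rather than one 7-day sum: the individual lags carry strictly more
information and are the only reading that yields exactly 20 ward-level
columns. Day-of-week and month enter the tree/kernel models as integer
codes (trees split integers natively); the ARMAX model instead receives
day-of-week indicator contrasts, as a linear model requires. Elapsed LOS is
aggregated by the mean (configurable to median). Rows exist from the 22nd
series day, when the deepest lag is available.

**Trend feature.** Locally weighted polynomial regression (degree 2,
tricube weights, span 0.75) over the ordered past discharges on the same
weekday, evaluated at the next same-weekday index — i.e. a one-step loess
extrapolation. With fewer than 5 observations the fit is replaced by the
plain mean. statsmodels' lowess is degree-1 and cannot extrapolate, so the
local weighted quadratic is implemented directly (weighted `polyfit` on the
span-nearest points); the newest point's tricube weight is floored at 1e-6
so the design never degenerates.

## Forecasters

- **Naive baselines:** same weekday last week; mean of the trailing 7
  days; mean of the trailing 21 days. The trailing-3-week mean is the
  strongest of the three and is the default improvement reference.
- **kNN pattern matching (from scratch):** the query is the vector of the
  last `p` daily discharges; every complete historical window of length `p`
  whose next-day value is observed is a candidate; Euclidean distance, ties
  broken toward the earlier window start (the method is otherwise
  nondeterministic). The k matched next-day values are combined by their
  median (`robust_median`, the default — the minimizer of absolute-error
  loss, robust to outlier-heavy counts) or a weighted mean
  (`weighted_quadratic`; uniform weights reduce to the plain mean). The
  median variant is unweighted. `(p, k)` are tuned by one-step-ahead RMSE
  on the last 20% of the training series; ties prefer smaller `p`, then
  smaller `k`. Default grids `p ∈ {2,3,7,14,21}`, `k ∈ {5,10,25,50}` keep a
  desk-scale run fast; wider scans are a constructor argument.
- **ARIMA / ARMAX (statsmodels adapters):** refit each day on the trailing
  90 days ("past 3 months") of discharges. Orders `(p, d, q)`,
  `p, q ≤ 2`, `d ≤ 1`, are selected by AICc; reselection runs every 28
  forecasts while coefficients are re-estimated daily — daily reselection
  is available (`order_reselect_every=1`) but costs ~12× for no measurable
  change on the synthetic series. ARMAX adds known exogenous regressors:
  day-of-week contrasts of the forecast day (Monday reference) and
  previous-day occupancy. A constant window short-circuits to that
  constant (differencing-safe); a non-finite forecast falls back to the
  trailing-week mean with a logged warning.
- **Random forest (scikit-learn adapter):** fit once on the training block
  (no daily refit). Variables-per-split is chosen by scanning the
  out-of-bag RMSE over `max_features ∈ {0.33, 0.5, 0.7, 1.0}`; 300 trees,
  minimum leaf 5, fixed recorded seed. Zero-variance columns are dropped
  with a logged list.
- **SVR (scikit-learn adapter):** RBF kernel; features standardized with
  training statistics only; `(C, ε, γ)` grid-searched to minimize RMSE on
  the last 20% of training rows (time-ordered split), with
  `C ∈ {0.1,1,10,100}`, `ε ∈ {0.1,0.5,1,2}` and γ centred on
  `1/(2·n_features)` ± one decade.
- **Feature importance:** permutation importance of the fitted forest on
  its training block (5 repeats, fixed seed), reported over all 108
  columns (dropped columns score 0).

## Numerical and design notes

- All randomness flows from explicit seeds: the simulator's `seed` field,
  the RF `random_state`, and the importance permutation seed; two runs with
  identical configuration are bit-identical.
- sMAPE uses the 200·|y−f|/(y+f) form; a pair with `y + f = 0` contributes
  0 (both sides agree on zero). For nonnegative series the statistic lies
  in [0, 200], attaining 200 whenever exactly one side is zero.
- The improvement column is `100·(MAE_ref − MAE_model)/MAE_ref` against a
  named baseline (default the trailing-3-week mean).
- Weekdays are indexed Mon=1..Sun=7 in every report.
- Problem sizes in the shipped test-suite checks (e.g. a 3-year simulation
  with a 120-day test block, 3 seeds, for the model-ordering property) are
  the package's chosen desk-scale defaults; the generator and evaluator
  accept arbitrary spans.

## Known limitations

- Single ward only; no transfers, no bed-level modelling, no capacity
  censoring of occupancy.
- The simulator's categorical attributes carry no signal about LOS, so the
  patient-level block helps the feature-based models mainly through roster
  size and elapsed-LOS composition; on real data those counts could matter
  more (or less).
- ARIMA/ARMAX order search is a small AICc grid, not a full seasonal
  specification search; with strong weekly signal the exogenous contrasts
  in ARMAX carry the seasonality instead.
- No prediction intervals, multi-step horizons, or formal tests of
  forecast-superiority; point forecasts and descriptive error metrics only.
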