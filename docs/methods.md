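# Methods

## Model and assumptions

The package treats a monthly revenue panel split into D strictly positive
categories as the product of a total and a composition, and models the two
separately on a pre-period training window:

* **Total.** `log y_t = β0 + β1·t + β_month(t) + ε_t`. The time covariate
  `t` is integer months since the training start (0-based). Month-of-year
  effects use treatment coding with January as the reference; predictions
  are invariant to this identification, and the chosen coding is recorded on
  the fit object so coefficients stay interpretable. Estimation is OLS on
  logs. No lognormal bias correction (+σ²/2) is applied at back-transform:
  the expectation is *defined* as exp(linear predictor) and the bootstrap
  carries the distributional statement, so predicted medians and intervals
  are internally consistent.
* **Composition.** Shares are mapped to D−1 isometric log-ratio (ILR)
  coordinates and each coordinate gets the same trend + seasonality OLS.
  All coordinates share identical regressors, so per-equation OLS coincides
  with the seemingly-unrelated-regressions estimator; cross-equation error
  correlation is captured afterwards in the residual covariance rather than
  in the point estimation.
* **Recombination.** `ŷ_ti = ŷ_t · π̂_ti`. Coherency (category expectations
  summing to the total) holds by construction, to floating-point precision,
  for point expectations and for every bootstrap draw.

Central assumptions: multivariate normality of the stacked
[log-total, ILR] errors, linearity of the long-term log trend, stable
seasonality, and independence of errors across months. The first is
checkable via interval calibration (below); the second via the
linear-vs-quadratic specification comparison; the last is *assumed*, not
addressed — receipts residuals show little autocorrelation at the monthly
horizon, but no block bootstrap is provided.

## ILR basis

The ILR contrast is the Helmert-derived orthonormal basis in the fixed
category order (beer, cider, spirits, wine) by default. The choice is
immaterial for any quantity on the revenue scale: any two orthonormal bases
differ by a rotation of the coordinate space, OLS is equivariant under that
rotation, and the inverse transform undoes it. This invariance is asserted
by test rather than assumed. The basis is parametric in D ≥ 2 and is
recorded in all fit outputs; a custom contrast matrix can be supplied via
config.

## Uncertainty

The D×D sample covariance (denominator n−1, no degrees-of-freedom
correction for the regression parameters — switchable via `ddof`) of the
stacked per-training-month residuals feeds a residual bootstrap. The
default variant samples parametrically from MVN(0, Σ̂); `method="resample"`
instead resamples whole residual rows jointly, preserving the empirical
joint distribution. Draws perturb the log-total and ILR predictors, are
back-transformed and recombined, so every draw is a coherent, positive
receipts path. Intervals are empirical quantiles across draws; the point is
the model expectation, not the draw mean. A numerical eigenvalue clip at 0
repairs covariance round-off; anything below −1e-10·trace is an error.

**Deliberately not propagated:** sampling error of the regression
coefficients. Monthly prediction intervals are nearly exact despite this
(the training windows are long relative to the 13 parameters per equation),
and the in-sample 95% coverage of ~0.95 confirms it. The omission *does*
matter for multi-year cumulative bands: with a 120-month training window
and a 5-year horizon, trend- and level-estimation error accumulates and the
residual-only cumulative interval is materially narrower than the true
predictive band. The cumulative calibration test therefore conditions on
the true expectation path; when interpreting real-data cumulative deficits,
the bands understate uncertainty at long horizons.

Cumulative deviation intervals are computed at the draw level (cumulate
observed − draw, then quantile). Summing monthly bounds is wrong in both
directions — it ignores the independence of month-level errors within a
path — and a test asserts the two constructions differ.

"Significance" of a month means its 95% deviation interval excludes zero.
No multiple-testing correction is applied across months; with ~60 forecast
months, ~3 false flags are expected under the null.

## Synthetic data generator

The generator draws from the model family itself: linear log trend
(default β1 = 0.0015/month ≈ 1.8%/year), a smooth seasonal pattern peaking
in December (amplitude 0.12 on the log scale, echoing pre-Christmas
clearance spikes), baseline shares (0.35, 0.05, 0.25, 0.35) for (beer,
cider, spirits, wine) with slow ILR drift, and MVN noise with standard
deviations (0.05, 0.015, 0.015, 0.015) on the [log-total, ILR] scale and a
0.2 common correlation. Totals come out near £1,000m/month. These defaults
are illustrative of the scale of the real series, not estimates of it.

Shocks are multiplicative on the revenue scale by default (applied as
log-scale offsets, so positivity is automatic); an additive-£m mode exists
with an explicit positivity check, used to inject exact-magnitude deficits.
Scenario presets: `null`, `lockdown` (−30%/+13% dips and rebounds in 2020–
21), `cost_of_living` (wine ramping to −26% through 2022, spirits −20% step
from Nov 2022), `forestalling` (+35% single month Aug 2023, −15% offset in
Sep–Oct).

What passing tests on generated data do **not** show: robustness to
features real receipts have and the generator lacks — residual
autocorrelation, outliers from duty-rate changes or administrative
reporting, gradual seasonal change, and genuine trend breaks. The
sensitivity machinery (configurable training cutoff) exists precisely
because the linear-trend assumption can fail in segments of real data.

## Numerical and design choices

* Problem sizes in the shipped checks: 120–240-month training windows,
  10,000 bootstrap draws for reported intervals (4,000 in the calibration
  simulation, which repeats 25 times), 200 replicates for parameter
  recovery, 100 for the trend-specification comparison.
* Zero or negative receipts are rejected by default (logs and log-ratios
  are undefined there); an explicit `floor_epsilon` clips with a loud
  warning.
* A training window must span ≥ 24 months and contain every calendar month,
  otherwise month effects are unidentified (rank error).
* Forecast months before the training origin require an explicit opt-in
  (`allow_pre_origin`); the CLI warns when extrapolating beyond 1.5× the
  training span.
* The deviation start month defaults to the first post-training month;
  deficits carry a negative sign everywhere.
* Ties/quantiles: empirical quantiles use numpy's default (linear
  interpolation); at extreme levels with few tail draws a warning is
  emitted rather than an error.

## Limitations

* Residual-only intervals (see above) — honest for monthly statements,
  optimistic for long-horizon cumulative ones.
* Independence across months is assumed; forestalling events violate it by
  construction (a spike borrows from the following months).
* The composition model cannot represent a category going to zero; the
  approach is for panels where every category stays strictly positive.
* Receipts measure duty cleared, not consumption; interpretation beyond the
  accounting (what caused a deficit) is out of scope for the package.
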