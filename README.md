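# dutycast

Counterfactual forecasting of monthly UK alcohol duty receipts — or any
strictly positive monthly revenue panel split into categories — to measure
how far observed receipts have drifted from a pre-period trend.

Alcohol duty receipts are a population-level proxy for alcohol sales: duty
is paid when products are cleared for sale, and HMRC publishes monthly
receipts separately for beer, cider, spirits and wine. To ask "how much
lower are receipts than they *would* have been?", one needs a counterfactual
expectation with honest uncertainty, and the category-level expectations
must add up to the total (coherency), otherwise the per-beverage story and
the overall story contradict each other.

## The model

Receipts are first expressed in constant prices with a retail price index.
Two regressions are then fitted on a training window (e.g. Jan 2010 – Dec
2019):

1. **Total trend.** Log total receipts follow a linear trend with
   month-of-year fixed effects,

   log ŷ_t = β₀ + β₁·t + β_month(t),

   where t counts months since the training start and January is the
   reference month.

2. **Composition.** The vector of beverage shares π_t lives on the 4-part
   simplex. Its isometric log-ratio (ILR) coordinates — an orthonormal
   log-ratio transform to ℝ³ — get the same trend + seasonality regression,
   one OLS per coordinate:

   ilr(π̂_t)_i = β₀ⁱ + β₁ⁱ·t + β_month(t)ⁱ.

3. **Recombination.** Expected receipts for beverage i are ŷ_ti = ŷ_t·π̂_ti.
   Because shares sum to one by construction, Σ_i ŷ_ti = ŷ_t exactly, for
   every month — and for every bootstrap draw.

4. **Uncertainty.** The per-month stacked residual vector
   [log-total residual, ILR residuals] has its sample covariance estimated
   from the training window. A residual bootstrap samples correlated errors
   from the fitted multivariate normal (or resamples residual rows jointly),
   perturbs the linear predictors, back-transforms and recombines. Empirical
   quantiles across draws give 95% prediction intervals for totals,
   categories, and every derived deviation.

5. **Deviations.** Monthly deviation = observed − expected (deficits
   negative). Cumulative deviations and their intervals are computed per
   draw, then quantiled — never by summing monthly bounds. Relative
   deviations divide by the (cumulative) expectation, in percent.

Everything is testable without external data because the package ships a
synthetic-panel generator drawn from exactly this model family, with known
coefficients and injectable shocks (lockdown dips/rebounds, cost-of-living
deficits, a one-month forestalling spike).

## Worked example

```python
import dutycast as dc

# a synthetic panel with a gradually deepening wine deficit from 2022 and a
# spirits step deficit from Nov 2022, on top of a log-linear seasonal trend
observed, truth = dc.generate(dc.scenario("cost_of_living", seed=11))

total_fit, comp_fit, expected, draws, report = dc.analyse(
    observed, training_end="2019-12", n_draws=10_000, seed=5)

print(f"{total_fit.beta1:.5f}")               # fitted log-trend slope per month
cum = report.cumulative["point"]["total"].iloc[-1]
rel = report.relative_cumulative["point"]["total"].iloc[-1]
```

This prints a fitted slope of `0.00143` per month (≈1.7%/year real growth;
the generator's truth is 0.0015) and reports a cumulative deviation since
January 2020 of **−3,708 £m** with 95% interval [−4,589, −2,994], i.e.
**−5.7%** of expected receipts — the injected cost-of-living deficit,
recovered with its uncertainty. Monthly wine deviations in mid-2023 sit
around −66 £m (−20% of expected wine receipts) and are flagged significant
(interval excluding zero) in all twelve months of 2023.

The same pipeline runs from the shell:

```sh
dutycast synth --scenario cost_of_living --seed 11 --out panel.csv
dutycast report --config analysis.yaml     # fit → forecast → bootstrap → report
```

where `analysis.yaml` names the receipts CSV (long or wide), the optional
price-index CSV, the training window, draw count, seed and output
directory. The bundle contains the fitted coefficients (JSON), expected
receipts and tidy deviation tables (CSV), a training-period
interval-coverage table, deviation figures and a run manifest; identical
config and seed reproduce the CSVs byte for byte.

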