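"""Deviation accounting: monthly, cumulative, relative, sensitivity."""

import numpy as np
import pytest

from dutycast import (
    GeneratorSpec,
    Shock,
    analyse,
    cumulative_deviation,
    generate,
    monthly_deviation,
    relative_deviation,
    run_sensitivity,
    scenario,
)
from dutycast.data_io import parse_month
from dutycast.errors import CoverageError, DomainError


@pytest.fixture(scope="module")
def null_report():
    observed, _ = generate(scenario("null", seed=10))
    *_, report = analyse(observed, training_end="2019-12", n_draws=2000, seed=1)
    return report


def test_observed_equal_expected_gives_zero_deviations(null_report):
    rep = null_report
    # rebuild with observed == expected: deviations vanish, nothing significant
    from dutycast.data_io import ReceiptsTable

    exp_table = ReceiptsTable(rep.expected.per_category, basis="deflated(2025-01)")
    rep0 = monthly_deviation(exp_table, rep.expected, rep.draws, level=0.95)
    assert np.allclose(rep0.monthly["point"].to_numpy(), 0.0, atol=1e-9)
    rep0 = relative_deviation(cumulative_deviation(rep0))
    assert np.allclose(rep0.relative_monthly["point"].to_numpy(), 0.0, atol=1e-9)
    assert not rep0.significant("monthly").any().any()


def test_category_deviations_sum_to_total(null_report):
    part = null_report.monthly["point"]
    cats = list(null_report.observed.categories)
    assert np.allclose(
        part[cats].sum(axis=1), part["total"], atol=1e-9 * part["total"].abs().max()
    )


def test_cumulative_is_running_sum(null_report):
    rep = null_report
    for name in rep.series_names:
        assert np.allclose(
            rep.cumulative["point"][name].to_numpy(),
            rep.monthly["point"][name].cumsum().to_numpy(),
            atol=1e-9,
        )
    # first differences give back the monthly series
    diffs = np.diff(rep.cumulative["point"]["total"].to_numpy())
    assert np.allclose(diffs, rep.monthly["point"]["total"].to_numpy()[1:], atol=1e-9)


def test_simple_running_sum_example(null_report):
    assert list(np.cumsum([10.0, -10.0, 5.0])) == [10.0, 0.0, 5.0]
    # (kept next to the draw-level construction checks for contrast)


def test_cumulative_bounds_are_draw_level_not_summed(null_report):
    rep = null_report
    summed_lower = rep.monthly["lower"]["total"].cumsum().to_numpy()
    draw_lower = rep.cumulative["lower"]["total"].to_numpy()
    # summing monthly bounds ignores within-path correlation and gives a
    # (much) wider band than the per-draw construction
    assert not np.allclose(summed_lower[1:], draw_lower[1:], rtol=1e-3)
    assert (draw_lower[5:] > summed_lower[5:]).all()


def test_relative_deviation_arithmetic(null_report):
    rep = null_report
    expect = rep.expected.per_category.copy()
    expect.insert(0, "total", rep.expected.total)
    manual = rep.monthly["point"] / expect.to_numpy() * 100.0
    assert np.allclose(rep.relative_monthly["point"].to_numpy(), manual.to_numpy())
    # -25 on an expectation of 100 is -25%
    assert (-25.0 / 100.0 * 100.0) == -25.0


def test_injected_wine_deficit_recovered():
    shock = Shock("wine", parse_month("2022-01"), parse_month("2025-01"),
                  -200.0, mode="additive")
    spec = GeneratorSpec(seed=4, shocks=(shock,))
    observed, _ = generate(spec)
    *_, rep = analyse(observed, training_end="2019-12", n_draws=4000, seed=2)
    months = rep.months
    hit = months >= parse_month("2022-01")
    wine_dev = rep.monthly["point"]["wine"].to_numpy()[hit]
    lo = rep.monthly["lower"]["wine"].to_numpy()[hit]
    hi = rep.monthly["upper"]["wine"].to_numpy()[hit]
    # injected magnitude sits inside the interval for nearly all months and
    # the average point estimate is close to -200
    inside = (lo <= -200.0) & (-200.0 <= hi)
    assert inside.mean() > 0.9
    assert abs(wine_dev.mean() + 200.0) < 40.0
    # relative deficit matches brute force against the expected wine path
    exp_wine = rep.expected.per_category["wine"].to_numpy()[hit]
    brute = wine_dev / exp_wine * 100.0
    got = rep.relative_monthly["point"]["wine"].to_numpy()[hit]
    assert np.allclose(got, brute, atol=1e-9)


def test_null_scenario_cumulative_interval_contains_zero_mostly():
    """Per-draw cumulative bands are calibrated under the null when residual
    error is the only error source (expectation = the generator's own path).

    With a refitted model the bands also absorb coefficient-estimation error,
    which the residual-only bootstrap deliberately does not propagate, so the
    calibration statement is made against the known truth path.
    """
    from dutycast.uncertainty import ResidualCovariance, draw_forecasts

    spec0 = scenario("null", seed=0)
    cov = ResidualCovariance(
        mean=np.zeros(4), cov=spec0.noise_cov(), residuals=np.zeros((1, 4))
    )
    basis = spec0.basis()
    first, last = parse_month("2020-01"), parse_month("2025-01")
    n_rep, covered = 40, 0
    for k in range(n_rep):
        observed, truth = generate(scenario("null", seed=600 + k))
        exp = truth.slice(first, last)
        draws = draw_forecasts(exp, cov, basis, n_draws=1000, seed=k)
        rep = cumulative_deviation(
            monthly_deviation(observed.window(first, last), exp, draws)
        )
        lo = rep.cumulative["lower"]["total"].iloc[-1]
        hi = rep.cumulative["upper"]["total"].iloc[-1]
        covered += int(lo <= 0.0 <= hi)
    assert covered / n_rep >= 0.93 - 3 * np.sqrt(0.95 * 0.05 / n_rep)


def test_start_month_outside_range_errors(null_report):
    with pytest.raises(CoverageError):
        cumulative_deviation(null_report, start="2019-01")


def test_sensitivity_default_cutoff_matches_main(null_report):
    observed = null_report.observed  # deviation-window slice of the panel
    full, _ = generate(scenario("null", seed=10))
    reports = run_sensitivity(full, ["2019-12"], n_draws=2000, seed=1)
    rep = reports["2019-12"]
    assert np.allclose(
        rep.monthly["point"].to_numpy(), null_report.monthly["point"].to_numpy()
    )
    assert np.allclose(
        rep.cumulative["lower"].to_numpy(), null_report.cumulative["lower"].to_numpy()
    )


def test_sensitivity_detects_trend_break():
    """A deficit starting Jan 2018 is visible to a pre-2018-trained model but
    absorbed when the training window spans the break."""
    shock = Shock("total", parse_month("2018-01"), parse_month("2025-01"), -0.15)
    spec = GeneratorSpec(seed=9, shocks=(shock,))
    observed, _ = generate(spec)
    early = run_sensitivity(observed, ["2017-12"], n_draws=1000, seed=3)["2017-12"]
    late_months = early.months >= parse_month("2018-01")
    rel = early.relative_monthly["point"]["total"].to_numpy()[late_months]
    assert np.median(rel) < -8.0  # deficit of ~14% shows up
    # training through 2021 absorbs part of the level shift
    absorbed = run_sensitivity(observed, ["2021-12"], n_draws=1000, seed=3)["2021-12"]
    rel2 = absorbed.relative_monthly["point"]["total"].to_numpy()
    assert np.median(np.abs(rel2)) < np.median(np.abs(rel))


def test_sensitivity_too_early_cutoff_errors():
    observed, _ = generate(scenario("null", seed=1))
    with pytest.raises(DomainError):
        run_sensitivity(observed, ["2010-06"], n_draws=10, seed=0)


def test_sign_convention_deficit_negative():
    shock = Shock("total", parse_month("2020-01"), parse_month("2025-01"), -0.3)
    observed, _ = generate(GeneratorSpec(seed=2, shocks=(shock,)))
    *_, rep = analyse(observed, training_end="2019-12", n_draws=500, seed=0)
    assert (rep.monthly["point"]["total"] < 0).mean() > 0.95
    assert rep.cumulative["point"]["total"].iloc[-1] < 0
    assert rep.significant("monthly")["total"].mean() > 0.8


def test_tidy_export_has_all_metrics(null_report):
    tidy = relative_deviation(null_report).to_tidy()
    assert set(tidy["metric"]) == {
        "monthly", "cumulative", "relative_monthly", "relative_cumulative"
    }
    assert set(tidy["series"]) == {"total", "beer", "cider", "spirits", "wine"}
    assert (tidy["lower"] <= tidy["upper"]).all()
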