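"""Residual covariance, bootstrap draws, intervals and coverage."""

import numpy as np
import pandas as pd
import pytest

from dutycast import (
    GeneratorSpec,
    draw_forecasts,
    estimate_residual_covariance,
    fit_composition_model,
    fit_total_model,
    generate,
    predict_expected,
    prediction_intervals,
    coverage_check,
)
from dutycast.data_io import parse_month
from dutycast.errors import AlignmentError, DomainError
from dutycast.uncertainty import PredictionInterval, ResidualCovariance

WIN = (parse_month("2010-01"), parse_month("2019-12"))


def _fits(observed):
    return (
        fit_total_model(observed, window=WIN),
        fit_composition_model(observed, window=WIN),
    )


def test_noiseless_covariance_is_zero(noiseless_panel):
    observed, _ = noiseless_panel
    cov = estimate_residual_covariance(*_fits(observed))
    assert np.abs(cov.cov).max() < 1e-12


def test_covariance_matches_direct_formula(null_panel):
    observed, _ = null_panel
    tfit, cfit = _fits(observed)
    cov = estimate_residual_covariance(tfit, cfit)
    stacked = np.column_stack(
        [tfit.residuals_log.to_numpy(), cfit.residuals_ilr.to_numpy()]
    )
    centred = stacked - stacked.mean(axis=0)
    brute = centred.T @ centred / (stacked.shape[0] - 1)
    assert np.allclose(cov.cov, brute, atol=1e-12)
    assert np.allclose(cov.cov, np.cov(stacked, rowvar=False), atol=1e-12)


def test_covariance_recovery_with_long_series():
    """Diagonal generator covariance recovered within 3 MC SEs elementwise."""
    sd = np.array([0.05, 0.02, 0.02, 0.02])
    spec = GeneratorSpec(
        start=parse_month("2000-01"), end=parse_month("2039-12"),  # 480 months
        noise_sd=sd, noise_corr=0.0, seed=21,
    )
    observed, _ = generate(spec)
    win = (spec.start, spec.end)
    tfit = fit_total_model(observed, window=win)
    cfit = fit_composition_model(observed, window=win)
    cov = estimate_residual_covariance(tfit, cfit)
    n, p = 480, 13  # months, regressors (const + trend + 11 month dummies)
    truth = np.diag(sd**2) * (n - p) / n  # OLS residuals shrink the variance
    # SE of a sample variance ~ sqrt(2/n)*sigma^2; off-diagonals ~ sigma_i*sigma_j/sqrt(n)
    for i in range(4):
        for j in range(4):
            se = (np.sqrt(2.0 / n) if i == j else 1.0 / np.sqrt(n)) * sd[i] * sd[j]
            assert abs(cov.cov[i, j] - truth[i, j]) < 3 * se


def test_mismatched_windows_raise(null_panel):
    observed, _ = null_panel
    tfit = fit_total_model(observed, window=WIN)
    cfit = fit_composition_model(observed, window=(WIN[0], parse_month("2018-12")))
    with pytest.raises(AlignmentError):
        estimate_residual_covariance(tfit, cfit)


def _expected_and_cov(observed, months=None):
    tfit, cfit = _fits(observed)
    cov = estimate_residual_covariance(tfit, cfit)
    months = months if months is not None else pd.period_range("2020-01", "2021-12", freq="M")
    return predict_expected(tfit, cfit, months), cov, cfit


def test_zero_covariance_draws_collapse_to_expectation(null_panel):
    observed, _ = null_panel
    expected, cov, cfit = _expected_and_cov(observed)
    zero = ResidualCovariance(
        mean=np.zeros(4), cov=np.zeros((4, 4)), residuals=np.zeros((120, 4))
    )
    draws = draw_forecasts(expected, zero, cfit, n_draws=50, seed=0)
    assert np.allclose(draws.totals, expected.total.to_numpy()[None, :], rtol=1e-12)
    assert np.allclose(
        draws.per_category, expected.per_category.to_numpy()[None, :, :], rtol=1e-12
    )
    with pytest.warns(UserWarning):
        iv = prediction_intervals(draws, level=0.95)
    assert np.allclose(iv.lower.to_numpy(), iv.upper.to_numpy())
    assert np.allclose(iv.lower.to_numpy(), iv.point.to_numpy())


@pytest.mark.parametrize("method", ["parametric", "resample"])
def test_same_seed_reproducible_different_seed_not(null_panel, method):
    observed, _ = null_panel
    expected, cov, cfit = _expected_and_cov(observed)
    d1 = draw_forecasts(expected, cov, cfit, n_draws=200, seed=7, method=method)
    d2 = draw_forecasts(expected, cov, cfit, n_draws=200, seed=7, method=method)
    d3 = draw_forecasts(expected, cov, cfit, n_draws=200, seed=8, method=method)
    assert np.array_equal(d1.per_category, d2.per_category)
    assert not np.array_equal(d1.per_category, d3.per_category)


def test_lognormal_tail_quantile_closed_form(null_panel):
    """With only log-total variance, the 97.5% quantile over the point
    expectation is exp(1.96*sigma) up to Monte-Carlo error."""
    observed, _ = null_panel
    expected, _, cfit = _expected_and_cov(observed)
    sigma = 0.05
    cov = np.zeros((4, 4))
    cov[0, 0] = sigma**2
    rc = ResidualCovariance(mean=np.zeros(4), cov=cov, residuals=np.zeros((120, 4)))
    draws = draw_forecasts(expected, rc, cfit, n_draws=100_000, seed=3)
    iv = prediction_intervals(draws, level=0.95)
    ratio = iv.upper["total"] / iv.point["total"]
    assert np.allclose(ratio, np.exp(1.959964 * sigma), rtol=3e-3)
    # shares carry no noise here, so category draws inherit the same ratio
    ratio_b = iv.upper["beer"] / iv.point["beer"]
    assert np.allclose(ratio_b, np.exp(1.959964 * sigma), rtol=3e-3)


def test_interval_width_monotone_in_covariance(null_panel):
    observed, _ = null_panel
    expected, cov, cfit = _expected_and_cov(observed)
    wider = ResidualCovariance(
        mean=cov.mean, cov=cov.cov * 4.0, residuals=cov.residuals
    )
    d1 = draw_forecasts(expected, cov, cfit, n_draws=4000, seed=5)
    d2 = draw_forecasts(expected, wider, cfit, n_draws=4000, seed=5)
    w1 = prediction_intervals(d1).upper - prediction_intervals(d1).lower
    w2 = prediction_intervals(d2).upper - prediction_intervals(d2).lower
    assert (w2.to_numpy() >= w1.to_numpy()).all()


def test_every_draw_is_coherent_and_positive(null_panel):
    observed, _ = null_panel
    expected, cov, cfit = _expected_and_cov(observed)
    draws = draw_forecasts(expected, cov, cfit, n_draws=500, seed=1)
    assert (draws.per_category > 0).all()
    gap = np.abs(draws.per_category.sum(axis=2) - draws.totals) / draws.totals
    assert gap.max() < 1e-9


def test_coverage_trivial_cases(null_panel):
    observed, _ = null_panel
    months = pd.period_range("2010-01", "2010-12", freq="M")
    obs = observed.values.loc[months].copy()
    obs.insert(0, "total", observed.total()[months])
    exact = PredictionInterval(
        level=0.95, lower=obs.copy(), point=obs.copy(), upper=obs.copy()
    )
    cov = coverage_check(observed, exact)
    assert (cov == 1.0).all()
    off = PredictionInterval(
        level=0.95, lower=obs + 1e9, point=obs + 1e9, upper=obs + 2e9
    )
    assert (coverage_check(observed, off) == 0.0).all()


def test_draws_long_export_shape(null_panel):
    observed, _ = null_panel
    expected, cov, cfit = _expected_and_cov(
        observed, months=pd.period_range("2020-01", "2020-06", freq="M")
    )
    draws = draw_forecasts(expected, cov, cfit, n_draws=10, seed=0)
    frame = draws.to_long_frame()
    assert set(frame.columns) == {"draw", "month", "series", "value"}
    assert len(frame) == 10 * 6 * 5  # draws x months x (total + 4 categories)


def test_invalid_draw_arguments(null_panel):
    observed, _ = null_panel
    expected, cov, cfit = _expected_and_cov(observed)
    with pytest.raises(DomainError):
        draw_forecasts(expected, cov, cfit, n_draws=0, seed=0)
    with pytest.raises(DomainError):
        draw_forecasts(expected, cov, cfit, n_draws=10, seed=0, method="jackknife")
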