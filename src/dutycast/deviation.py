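"""Observed-minus-expected deviation accounting.

Deviations are the simple difference between observed and expected
receipts, per month and series (total plus each beverage), with bootstrap
interval bounds. Cumulative deviations and their intervals are computed at
the draw level — cumulate observed minus each bootstrap path, then take
quantiles — never by summing monthly bounds, which would ignore the
within-path correlation. Relative deviations divide by the corresponding
expected (or cumulative expected) value, in percent.

Sign convention: a deficit (observed below expectation) is negative
everywhere. A month is flagged "significant" when the deviation interval
excludes zero; no multiple-testing correction is applied across months.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .composition import IlrBasis
from .data_io import ReceiptsTable, parse_month
from .errors import AlignmentError, CoverageError, DomainError
from .models import (
    ExpectedReceipts,
    fit_composition_model,
    fit_total_model,
    predict_expected,
)
from .uncertainty import (
    TOTAL,
    ForecastDraws,
    draw_forecasts,
    estimate_residual_covariance,
)

__all__ = [
    "DeviationReport",
    "monthly_deviation",
    "cumulative_deviation",
    "relative_deviation",
    "analyse",
    "run_sensitivity",
]


def _quantile_bounds(dev_draws: np.ndarray, level: float):
    """Lower/upper deviation bounds from (n_draws, n_months) deviation draws."""
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    return np.quantile(dev_draws, lo_q, axis=0), np.quantile(dev_draws, hi_q, axis=0)


@dataclass(frozen=True)
class DeviationReport:
    """Monthly/cumulative/relative deviations with interval bounds.

    Each metric is a dict of three DataFrames (months x series):
    ``point``, ``lower``, ``upper``. Populated incrementally by
    :func:`monthly_deviation`, :func:`cumulative_deviation` and
    :func:`relative_deviation`.
    """

    observed: ReceiptsTable
    expected: ExpectedReceipts
    draws: ForecastDraws
    level: float
    monthly: dict = field(default_factory=dict)
    cumulative: dict = field(default_factory=dict)
    relative_monthly: dict = field(default_factory=dict)
    relative_cumulative: dict = field(default_factory=dict)
    start: pd.Period | None = None

    @property
    def months(self) -> pd.PeriodIndex:
        return self.monthly["point"].index

    @property
    def series_names(self) -> tuple[str, ...]:
        return (TOTAL, *self.observed.categories)

    def significant(self, metric: str = "monthly") -> pd.DataFrame:
        """True where the interval for the deviation excludes zero."""
        part = getattr(self, metric)
        return (part["lower"] > 0) | (part["upper"] < 0)

    def to_tidy(self) -> pd.DataFrame:
        """Long CSV-ready frame: month, series, metric, point, lower, upper."""
        rows = []
        for metric in ("monthly", "cumulative", "relative_monthly", "relative_cumulative"):
            part = getattr(self, metric)
            if not part:
                continue
            for name in part["point"].columns:
                rows.append(
                    pd.DataFrame(
                        {
                            "month": part["point"].index.astype(str),
                            "series": name,
                            "metric": metric,
                            "point": part["point"][name].to_numpy(),
                            "lower": part["lower"][name].to_numpy(),
                            "upper": part["upper"][name].to_numpy(),
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


def _observed_frame(observed: ReceiptsTable, months: pd.PeriodIndex) -> pd.DataFrame:
    missing = months.difference(observed.months)
    if len(missing):
        raise AlignmentError(f"observed table missing months {list(missing.astype(str))}")
    obs = observed.values.loc[months].copy()
    obs.insert(0, TOTAL, observed.total()[months])
    return obs


def monthly_deviation(
    observed: ReceiptsTable,
    expected: ExpectedReceipts,
    draws: ForecastDraws,
    level: float = 0.95,
) -> DeviationReport:
    """Monthly observed − expected with bootstrap interval bounds.

    The upper deviation bound comes from the lower draw quantile and vice
    versa: bounds are quantiles of observed − draw.
    """
    months = expected.months
    if not draws.months.equals(months):
        raise AlignmentError("draws and expectation cover different months")
    obs = _observed_frame(observed, months)
    point, lower, upper = {}, {}, {}
    exp_frame = expected.per_category.copy()
    exp_frame.insert(0, TOTAL, expected.total)
    for name in (TOTAL, *observed.categories):
        o = obs[name].to_numpy()
        point[name] = o - exp_frame[name].to_numpy()
        lo, hi = _quantile_bounds(o[None, :] - draws.series(name), level)
        lower[name], upper[name] = lo, hi
    part = {
        "point": pd.DataFrame(point, index=months),
        "lower": pd.DataFrame(lower, index=months),
        "upper": pd.DataFrame(upper, index=months),
    }
    return DeviationReport(
        observed=observed, expected=expected, draws=draws, level=level, monthly=part
    )


def cumulative_deviation(report: DeviationReport, start=None) -> DeviationReport:
    """Add running-sum deviations since ``start`` (default: first month).

    Interval bounds are quantiled over per-draw cumulative deviations,
    so within-path correlation is propagated correctly.
    """
    if not report.monthly:
        raise DomainError("monthly deviations must be computed first")
    months = report.months
    start = months[0] if start is None else parse_month(start)
    if start not in months:
        raise CoverageError(f"start {start} outside deviation months")
    keep = months[months >= start]
    obs = _observed_frame(report.observed, keep)
    point, lower, upper = {}, {}, {}
    for name in report.series_names:
        point[name] = report.monthly["point"].loc[keep, name].cumsum().to_numpy()
        draw_m = report.draws.series(name)[:, months >= start]
        dev_draws = np.cumsum(obs[name].to_numpy()[None, :] - draw_m, axis=1)
        lower[name], upper[name] = _quantile_bounds(dev_draws, report.level)
    part = {
        "point": pd.DataFrame(point, index=keep),
        "lower": pd.DataFrame(lower, index=keep),
        "upper": pd.DataFrame(upper, index=keep),
    }
    return replace(report, cumulative=part, start=start)


def relative_deviation(report: DeviationReport) -> DeviationReport:
    """Add deviations as a percentage of the expected path.

    Monthly deviations divide by the month's expectation; cumulative
    deviations by the cumulative expectation since the start month.
    """
    if not report.monthly:
        raise DomainError("monthly deviations must be computed first")
    exp_frame = report.expected.per_category.copy()
    exp_frame.insert(0, TOTAL, report.expected.total)
    if (exp_frame <= 0).any().any():
        raise DomainError("relative deviation undefined for non-positive expectation")
    rel_m = {
        k: df / exp_frame.loc[df.index, df.columns].to_numpy() * 100.0
        for k, df in report.monthly.items()
    }
    out = replace(report, relative_monthly=rel_m)
    if report.cumulative:
        keep = report.cumulative["point"].index
        cum_exp = exp_frame.loc[keep].cumsum()
        rel_c = {
            k: df / cum_exp[df.columns].to_numpy() * 100.0
            for k, df in report.cumulative.items()
        }
        out = replace(out, relative_cumulative=rel_c)
    return out


def analyse(
    receipts: ReceiptsTable,
    training_end,
    training_start=None,
    forecast_end=None,
    deviation_start=None,
    basis: IlrBasis | None = None,
    trend: str = "linear",
    n_draws: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
    method: str = "parametric",
):
    """Full pipeline: fit on the training window, forecast, bootstrap,
    and report deviations from ``deviation_start`` (default: first month
    after training) onward.

    Returns ``(total_fit, comp_fit, expected, draws, report)`` where
    ``expected``/``draws`` span the whole series (training + forecast) and
    the report covers the deviation window.
    """
    training_start = (
        receipts.months[0] if training_start is None else parse_month(training_start)
    )
    training_end = parse_month(training_end)
    forecast_end = (
        receipts.months[-1] if forecast_end is None else parse_month(forecast_end)
    )
    window = (training_start, training_end)
    total_fit = fit_total_model(receipts, window=window, trend=trend)
    comp_fit = fit_composition_model(receipts, window=window, basis=basis, trend=trend)
    cov = estimate_residual_covariance(total_fit, comp_fit)
    all_months = pd.period_range(training_start, forecast_end, freq="M")
    expected = predict_expected(total_fit, comp_fit, all_months)
    draws = draw_forecasts(expected, cov, comp_fit, n_draws=n_draws, seed=seed, method=method)
    dev_start = (
        training_end + 1 if deviation_start is None else parse_month(deviation_start)
    )
    dev_months = all_months[all_months >= dev_start]
    if len(dev_months) == 0:
        raise DomainError("no months after the training window to assess")
    dev_expected = predict_expected(total_fit, comp_fit, dev_months)
    sel = np.isin(all_months.asi8, dev_months.asi8)
    dev_draws = ForecastDraws(
        months=dev_months,
        categories=draws.categories,
        totals=draws.totals[:, sel],
        per_category=draws.per_category[:, sel, :],
        seed=seed,
        method=method,
        expected=dev_expected,
    )
    report = monthly_deviation(receipts.window(dev_start, forecast_end), dev_expected,
                               dev_draws, level=level)
    report = relative_deviation(cumulative_deviation(report))
    return total_fit, comp_fit, expected, draws, report


def run_sensitivity(
    receipts: ReceiptsTable,
    cutoffs,
    **kwargs,
) -> dict[str, DeviationReport]:
    """Re-run the full pipeline for alternative training-end months.

    Each cutoff must leave at least 24 training months. Reports are keyed
    by the cutoff month string.
    """
    out = {}
    for cutoff in cutoffs:
        cutoff = parse_month(cutoff)
        n_train = (cutoff - receipts.months[0]).n + 1
        if n_train < 24:
            raise DomainError(f"cutoff {cutoff} leaves only {n_train} training months")
        *_, report = analyse(receipts, training_end=cutoff, **kwargs)
        out[str(cutoff)] = report
    return out
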