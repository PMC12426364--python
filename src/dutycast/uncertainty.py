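"""Residual-bootstrap prediction intervals.

The joint error of the two regressions is summarised by the sample
covariance of the stacked per-month residual vector
``[log-total residual, ILR residuals]`` — a D-vector per training month for
D beverage categories. Forecast uncertainty is propagated by a residual
bootstrap: for each forecast month and draw, a D-vector of errors is sampled
(parametrically from a multivariate normal with that covariance, or by
jointly resampling observed residual rows), added to the log-total and ILR
linear predictors, back-transformed, and recombined. Every draw therefore
satisfies coherency exactly, so interval endpoints of any derived sum are
internally consistent.

Only residual error is propagated; sampling uncertainty in the regression
coefficients is not (a documented limitation). Prediction intervals are
empirical quantiles across draws; the reported point is the model
expectation, not the draw mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .composition import IlrBasis, ilr_inverse, ilr_transform
from .data_io import ReceiptsTable
from .errors import AlignmentError, DomainError, NumericalError
from .models import CompositionModelFit, ExpectedReceipts, TotalModelFit

__all__ = [
    "ResidualCovariance",
    "ForecastDraws",
    "PredictionInterval",
    "estimate_residual_covariance",
    "draw_forecasts",
    "prediction_intervals",
    "coverage_check",
]

TOTAL = "total"


@dataclass(frozen=True)
class ResidualCovariance:
    """Mean and covariance of stacked [log-total, ILR] residuals.

    Keeps the raw per-month residual rows so the row-resampling bootstrap
    variant can draw from the empirical joint distribution.
    """

    mean: np.ndarray  # (D,), approx. zero for OLS with intercept
    cov: np.ndarray  # (D, D), symmetric PSD
    residuals: np.ndarray  # (n_months, D) stacked rows

    def __post_init__(self) -> None:
        c = np.asarray(self.cov, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise DomainError("covariance must be square")
        if not np.allclose(c, c.T, atol=1e-12):
            raise NumericalError("covariance not symmetric")

    @property
    def dimension(self) -> int:
        return self.cov.shape[0]

    @property
    def n_months(self) -> int:
        return self.residuals.shape[0]


def estimate_residual_covariance(
    total_fit: TotalModelFit, comp_fit: CompositionModelFit, ddof: int = 1
) -> ResidualCovariance:
    """Sample covariance of the per-month stacked residual vectors.

    Denominator ``n - ddof`` (default n-1); no degrees-of-freedom correction
    for the number of regression parameters is applied.
    """
    if not total_fit.residuals_log.index.equals(comp_fit.residuals_ilr.index):
        raise AlignmentError("total and composition residuals cover different months")
    stacked = np.column_stack(
        [total_fit.residuals_log.to_numpy(), comp_fit.residuals_ilr.to_numpy()]
    )
    n = stacked.shape[0]
    mean = stacked.mean(axis=0)
    centred = stacked - mean
    cov = centred.T @ centred / (n - ddof)
    return ResidualCovariance(mean=mean, cov=cov, residuals=stacked)


def _psd_factor(cov: np.ndarray) -> np.ndarray:
    """Square root of a PSD matrix, repairing tiny negative eigenvalues."""
    vals, vecs = np.linalg.eigh(cov)
    trace = float(np.trace(cov))
    if vals.min() < -1e-10 * max(trace, 1e-300):
        raise NumericalError(
            f"residual covariance is not PSD (min eigenvalue {vals.min():.3g})"
        )
    if vals.min() < 0:
        warnings.warn("clipping tiny negative covariance eigenvalues at 0", stacklevel=2)
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


@dataclass(frozen=True)
class ForecastDraws:
    """Bootstrap ensemble of receipts paths.

    ``totals`` has shape (n_draws, n_months); ``per_category`` has shape
    (n_draws, n_months, D) and sums to ``totals`` over the last axis for
    every single draw.
    """

    months: pd.PeriodIndex
    categories: tuple[str, ...]
    totals: np.ndarray
    per_category: np.ndarray
    seed: int
    method: str
    expected: ExpectedReceipts

    @property
    def n_draws(self) -> int:
        return self.totals.shape[0]

    def series(self, name: str) -> np.ndarray:
        """Draw matrix (n_draws, n_months) for 'total' or a category."""
        if name == TOTAL:
            return self.totals
        return self.per_category[:, :, self.categories.index(name)]

    @property
    def series_names(self) -> tuple[str, ...]:
        return (TOTAL, *self.categories)

    def to_long_frame(self) -> pd.DataFrame:
        """Tidy export (draw, month, series, value) for external plotting."""
        frames = []
        for name in self.series_names:
            m = self.series(name)
            frames.append(
                pd.DataFrame(
                    {
                        "draw": np.repeat(np.arange(self.n_draws), len(self.months)),
                        "month": np.tile(self.months.astype(str), self.n_draws),
                        "series": name,
                        "value": m.ravel(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def draw_forecasts(
    expected: ExpectedReceipts,
    cov: ResidualCovariance,
    basis: "IlrBasis | CompositionModelFit",
    n_draws: int = 10_000,
    seed: int = 0,
    method: str = "parametric",
) -> ForecastDraws:
    """Residual bootstrap around the expected receipts.

    ``method='parametric'`` samples errors from MVN(0, cov);
    ``method='resample'`` jointly resamples observed stacked residual rows
    (preserving their empirical joint distribution). Same seed, same draws.
    ``basis`` may be an :class:`IlrBasis` or a fitted composition model
    (whose basis is then used).
    """
    basis = getattr(basis, "basis", basis)
    if n_draws < 1:
        raise DomainError("n_draws must be >= 1")
    d = cov.dimension
    if d != len(expected.per_category.columns):
        raise DomainError("covariance dimension does not match category count")
    months = expected.months
    n_months = len(months)
    rng = np.random.default_rng(seed)

    if method == "parametric":
        factor = _psd_factor(cov.cov)
        eps = rng.standard_normal((n_draws, n_months, d)) @ factor.T
    elif method == "resample":
        idx = rng.integers(0, cov.n_months, size=(n_draws, n_months))
        eps = cov.residuals[idx]  # joint rows keep cross-series correlation
    else:
        raise DomainError(f"unknown draw method {method!r}")

    log_total = np.log(expected.total.to_numpy())
    z = ilr_transform(expected.shares.to_numpy(), basis)
    totals = np.exp(log_total[None, :] + eps[:, :, 0])
    shares = ilr_inverse(z[None, :, :] + eps[:, :, 1:], basis)
    per_category = totals[:, :, None] * shares
    return ForecastDraws(
        months=months,
        categories=tuple(expected.per_category.columns),
        totals=totals,
        per_category=per_category,
        seed=seed,
        method=method,
        expected=expected,
    )


@dataclass(frozen=True)
class PredictionInterval:
    """Per-month lower/point/upper for the total and each category."""

    level: float
    lower: pd.DataFrame  # months x series
    point: pd.DataFrame
    upper: pd.DataFrame

    def __post_init__(self) -> None:
        if not (self.lower <= self.upper + 1e-9).all().all():
            raise NumericalError("interval ordering violated (lower <= upper)")
        if not ((self.lower <= self.point + 1e-9).all().all()
                and (self.point <= self.upper + 1e-9).all().all()):
            # can only happen for degenerate levels where the interval
            # collapses to the draw median away from the model expectation
            warnings.warn("model expectation lies outside the bootstrap interval",
                          stacklevel=2)


def prediction_intervals(draws: ForecastDraws, level: float = 0.95) -> PredictionInterval:
    """Empirical bootstrap prediction intervals at the given level.

    The point is the model expectation (recombined from the two fits), not
    the mean of the draws.
    """
    if not 0 <= level < 1:
        raise DomainError("level must be in [0, 1)")
    tail = draws.n_draws * (1 - level) / 2
    if tail < 50:
        warnings.warn(
            f"only ~{tail:.0f} draws in each tail at level {level}; "
            "quantiles will be noisy",
            stacklevel=2,
        )
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    lower, upper, point = {}, {}, {}
    exp = draws.expected
    for name in draws.series_names:
        m = draws.series(name)
        lower[name] = np.quantile(m, lo_q, axis=0)
        upper[name] = np.quantile(m, hi_q, axis=0)
        point[name] = (
            exp.total if name == TOTAL else exp.per_category[name]
        ).to_numpy()
    idx = draws.months
    return PredictionInterval(
        level=level,
        lower=pd.DataFrame(lower, index=idx),
        point=pd.DataFrame(point, index=idx),
        upper=pd.DataFrame(upper, index=idx),
    )


def coverage_check(
    receipts: ReceiptsTable,
    intervals: PredictionInterval,
    window: tuple | None = None,
) -> pd.Series:
    """Fraction of months whose observed value lies inside the interval.

    Returned per series ('total' plus each category). The training-period
    coverage of nominal 95% intervals is the calibration diagnostic.
    """
    table = receipts.window(*window) if window else receipts
    months = table.months.intersection(intervals.point.index)
    if len(months) == 0:
        raise AlignmentError("no overlap between observed months and intervals")
    obs = table.values.loc[months].copy()
    obs[TOTAL] = table.total()[months]
    out = {}
    for name in intervals.point.columns:
        inside = (intervals.lower.loc[months, name] <= obs[name]) & (
            obs[name] <= intervals.upper.loc[months, name]
        )
        out[name] = float(inside.mean())
    return pd.Series(out, name="coverage")
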