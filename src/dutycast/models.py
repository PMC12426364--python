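"""Trend models for total receipts and beverage composition.

Two regressions fitted on a pre-period training window:

* total model — OLS of log total receipts on an integer month index
  (months elapsed since the training start) and month-of-year fixed
  effects, so ``log y_t = b0 + b1*t + b_month`` (optionally with a
  quadratic term for specification checks);
* composition model — the same regression applied independently to each
  ILR coordinate of the beverage share vector.

Expected receipts for any month recombine the two:
``y_hat_ti = y_hat_t * pi_hat_ti``, which makes category expectations sum
to the total expectation exactly (coherency) for every month, and equally
for every bootstrap draw built on the same construction.

Month effects use treatment coding with January as the reference (January
effect fixed at 0); predictions are invariant to this identification choice.
No lognormal bias correction is applied when exponentiating: the expectation
is defined as exp(linear predictor), and the bootstrap carries the
distributional statement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .composition import IlrBasis, helmert_basis, ilr_inverse, ilr_transform
from .data_io import ReceiptsTable, parse_month
from .errors import AlignmentError, DomainError, NumericalError

__all__ = [
    "TotalModelFit",
    "CompositionModelFit",
    "ExpectedReceipts",
    "fit_total_model",
    "fit_composition_model",
    "predict_expected",
    "evaluate_trend_specifications",
    "fits_to_json",
    "fits_from_json",
]

TRENDS = ("linear", "quadratic")


def _design(months: pd.PeriodIndex, origin: pd.Period, trend: str) -> np.ndarray:
    """Regression design: [1, t, (t^2), Feb..Dec dummies], t 0-based from origin."""
    if trend not in TRENDS:
        raise DomainError(f"trend must be one of {TRENDS}, got {trend!r}")
    t = np.asarray([(m - origin).n for m in months], dtype=float)
    cols = [np.ones_like(t), t]
    if trend == "quadratic":
        cols.append(t**2)
    moy = np.asarray([m.month for m in months])
    for month_of_year in range(2, 13):  # January is the reference level
        cols.append((moy == month_of_year).astype(float))
    return np.column_stack(cols)


def _check_window(months: pd.PeriodIndex) -> None:
    if len(months) < 24:
        raise DomainError(f"training window has {len(months)} months; need >= 24")
    present = {m.month for m in months}
    if present != set(range(1, 13)):
        missing = sorted(set(range(1, 13)) - present)
        raise NumericalError(
            f"calendar months {missing} absent from training window; "
            "month effects are not identified"
        )


def _unpack(params: np.ndarray, trend: str):
    k = 2 if trend == "linear" else 3
    beta0 = float(params[0])
    beta_trend = np.asarray(params[1:k], dtype=float)
    month_effects = np.concatenate([[0.0], params[k:]])  # Jan = 0
    return beta0, beta_trend, month_effects


@dataclass(frozen=True)
class TotalModelFit:
    """Fitted log-linear total-receipts model."""

    beta0: float
    beta_trend: np.ndarray  # (1,) linear or (2,) quadratic, per-month scale
    month_effects: np.ndarray  # 12 effects, January fixed at 0
    origin: pd.Period  # month with time index 0
    window: tuple[pd.Period, pd.Period]
    residuals_log: pd.Series  # per training month, log scale
    trend: str = "linear"

    @property
    def beta1(self) -> float:
        """Slope of the log-linear long-term trend, per month."""
        return float(self.beta_trend[0])

    def linear_predictor(self, months: pd.PeriodIndex) -> np.ndarray:
        t = np.asarray([(m - self.origin).n for m in months], dtype=float)
        lp = self.beta0 + self.beta_trend[0] * t
        if self.trend == "quadratic":
            lp = lp + self.beta_trend[1] * t**2
        moy = np.asarray([m.month for m in months])
        return lp + self.month_effects[moy - 1]

    def predict(self, months: pd.PeriodIndex) -> pd.Series:
        """Expected total receipts, £m (exp of the linear predictor)."""
        return pd.Series(np.exp(self.linear_predictor(months)), index=months)


@dataclass(frozen=True)
class CompositionModelFit:
    """Per-ILR-coordinate trend + seasonality regressions of beverage shares."""

    beta0: np.ndarray  # (D-1,)
    beta_trend: np.ndarray  # (D-1, 1) or (D-1, 2)
    month_effects: np.ndarray  # (D-1, 12), January column 0
    basis: IlrBasis
    categories: tuple[str, ...]
    origin: pd.Period
    window: tuple[pd.Period, pd.Period]
    residuals_ilr: pd.DataFrame  # months x (D-1)
    trend: str = "linear"

    def linear_predictor(self, months: pd.PeriodIndex) -> np.ndarray:
        """(n_months, D-1) ILR-scale predictor."""
        t = np.asarray([(m - self.origin).n for m in months], dtype=float)
        lp = self.beta0[None, :] + t[:, None] * self.beta_trend[:, 0][None, :]
        if self.trend == "quadratic":
            lp = lp + (t**2)[:, None] * self.beta_trend[:, 1][None, :]
        moy = np.asarray([m.month for m in months])
        return lp + self.month_effects[:, moy - 1].T

    def predict_shares(self, months: pd.PeriodIndex) -> pd.DataFrame:
        """Expected composition per month; rows are valid unit-sum shares."""
        shares = ilr_inverse(self.linear_predictor(months), self.basis)
        return pd.DataFrame(shares, index=months, columns=list(self.categories))


@dataclass(frozen=True)
class ExpectedReceipts:
    """Coherent expected receipts: per-category values sum to the total."""

    total: pd.Series  # y_hat_t, £m
    per_category: pd.DataFrame  # y_hat_ti, £m
    shares: pd.DataFrame  # pi_hat_ti
    basis_label: str
    window: tuple[pd.Period, pd.Period]

    @property
    def months(self) -> pd.PeriodIndex:
        return self.total.index

    def __post_init__(self) -> None:
        gap = np.abs(self.per_category.sum(axis=1) - self.total) / self.total
        if (gap > 1e-9).any():
            raise NumericalError("coherency violated: category sum != total")

    def slice(self, first: pd.Period, last: pd.Period) -> "ExpectedReceipts":
        """Restrict to an inclusive month range."""
        return ExpectedReceipts(
            total=self.total.loc[first:last],
            per_category=self.per_category.loc[first:last],
            shares=self.shares.loc[first:last],
            basis_label=self.basis_label,
            window=self.window,
        )


def fit_total_model(
    receipts: ReceiptsTable,
    window: tuple | None = None,
    trend: str = "linear",
) -> TotalModelFit:
    """OLS of log total receipts on trend and month-of-year effects."""
    table = receipts.window(*window) if window else receipts
    months = table.months
    _check_window(months)
    total = table.total().to_numpy()
    if (total <= 0).any():
        raise DomainError("non-positive total receipts in training window")
    x = _design(months, months[0], trend)
    fit = sm.OLS(np.log(total), x).fit()
    beta0, beta_trend, month_effects = _unpack(fit.params, trend)
    return TotalModelFit(
        beta0=beta0,
        beta_trend=beta_trend,
        month_effects=month_effects,
        origin=months[0],
        window=(months[0], months[-1]),
        residuals_log=pd.Series(fit.resid, index=months),
        trend=trend,
    )


def fit_composition_model(
    receipts: ReceiptsTable,
    window: tuple | None = None,
    basis: IlrBasis | None = None,
    trend: str = "linear",
) -> CompositionModelFit:
    """Independent OLS per ILR coordinate of the monthly share vectors.

    All coordinates share identical regressors, so equation-by-equation OLS
    coincides with the seemingly-unrelated-regressions estimator; the
    cross-coordinate error correlation is captured afterwards in the
    residual covariance.
    """
    table = receipts.window(*window) if window else receipts
    months = table.months
    _check_window(months)
    basis = basis or helmert_basis(len(table.categories))
    if basis.n_parts != len(table.categories):
        raise DomainError("basis dimension does not match category count")
    z = ilr_transform(table.shares(), basis)  # (n, D-1)
    x = _design(months, months[0], trend)
    k = 2 if trend == "linear" else 3
    fits = [sm.OLS(z[:, j], x).fit() for j in range(z.shape[1])]
    params = np.column_stack([f.params for f in fits])  # (p, D-1)
    resid = np.column_stack([f.resid for f in fits])
    beta0 = params[0].astype(float)
    beta_trend = params[1:k].T.astype(float)
    month_effects = np.hstack(
        [np.zeros((basis.n_parts - 1, 1)), params[k:].T]
    )
    return CompositionModelFit(
        beta0=beta0,
        beta_trend=beta_trend,
        month_effects=month_effects,
        basis=basis,
        categories=table.categories,
        origin=months[0],
        window=(months[0], months[-1]),
        residuals_ilr=pd.DataFrame(
            resid, index=months, columns=[f"ilr{i+1}" for i in range(basis.n_parts - 1)]
        ),
        trend=trend,
    )


def predict_expected(
    total_fit: TotalModelFit,
    comp_fit: CompositionModelFit,
    months,
    allow_pre_origin: bool = False,
) -> ExpectedReceipts:
    """Recombine the two fits into coherent per-category expectations."""
    if total_fit.origin != comp_fit.origin or total_fit.window != comp_fit.window:
        raise AlignmentError("total and composition fits use different windows")
    months = pd.PeriodIndex(months, freq="M")
    if not allow_pre_origin and (months < total_fit.origin).any():
        raise DomainError(
            f"months before training origin {total_fit.origin}; "
            "set allow_pre_origin=True to extrapolate backwards"
        )
    total = total_fit.predict(months)
    shares = comp_fit.predict_shares(months)
    per_category = shares.mul(total, axis=0)
    return ExpectedReceipts(
        total=total,
        per_category=per_category,
        shares=shares,
        basis_label=comp_fit.basis.label,
        window=total_fit.window,
    )


def evaluate_trend_specifications(
    receipts: ReceiptsTable,
    window: tuple | None = None,
    holdout_months: int = 24,
    specs: tuple[str, ...] = TRENDS,
) -> pd.DataFrame:
    """Out-of-sample forecast-error comparison of trend specifications.

    Fits each spec on the head of the window, forecasts total receipts over
    the held-out tail, and reports mean absolute and root-mean-square
    forecast error on the revenue (£m) scale.
    """
    table = receipts.window(*window) if window else receipts
    n = len(table.months)
    if holdout_months < 1 or n - holdout_months < 24:
        raise DomainError(
            f"degenerate split: {n} months with {holdout_months} held out"
        )
    head = table.window(table.months[0], table.months[n - holdout_months - 1])
    tail_months = table.months[n - holdout_months :]
    observed = table.total()[tail_months]
    rows = {}
    for spec in specs:
        fit = fit_total_model(head, trend=spec)
        err = fit.predict(tail_months) - observed
        rows[spec] = {
            "mae": float(np.abs(err).mean()),
            "rmse": float(np.sqrt((err**2).mean())),
            "n_train": len(head.months),
            "n_test": len(tail_months),
        }
    return pd.DataFrame(rows).T


# --- JSON round-trip of fitted models -------------------------------------


def fits_to_json(total_fit: TotalModelFit, comp_fit: CompositionModelFit, path) -> None:
    """Serialise both fits (coefficients, window, basis, residuals) to JSON."""
    doc = {
        "total": {
            "beta0": total_fit.beta0,
            "beta_trend": total_fit.beta_trend.tolist(),
            "month_effects": total_fit.month_effects.tolist(),
            "origin": str(total_fit.origin),
            "window": [str(m) for m in total_fit.window],
            "trend": total_fit.trend,
            "residuals_log": {
                str(m): v for m, v in total_fit.residuals_log.items()
            },
        },
        "composition": {
            "beta0": comp_fit.beta0.tolist(),
            "beta_trend": comp_fit.beta_trend.tolist(),
            "month_effects": comp_fit.month_effects.tolist(),
            "basis": {
                "label": comp_fit.basis.label,
                "matrix": comp_fit.basis.matrix.tolist(),
            },
            "categories": list(comp_fit.categories),
            "origin": str(comp_fit.origin),
            "window": [str(m) for m in comp_fit.window],
            "trend": comp_fit.trend,
            "residuals_ilr": {
                str(m): row.tolist()
                for m, row in zip(
                    comp_fit.residuals_ilr.index,
                    comp_fit.residuals_ilr.to_numpy(),
                )
            },
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def fits_from_json(path) -> tuple[TotalModelFit, CompositionModelFit]:
    """Load fits written by :func:`fits_to_json`."""
    doc = json.loads(Path(path).read_text())
    t = doc["total"]
    total_fit = TotalModelFit(
        beta0=float(t["beta0"]),
        beta_trend=np.asarray(t["beta_trend"], dtype=float),
        month_effects=np.asarray(t["month_effects"], dtype=float),
        origin=parse_month(t["origin"]),
        window=tuple(parse_month(m) for m in t["window"]),
        residuals_log=pd.Series(
            list(t["residuals_log"].values()),
            index=pd.PeriodIndex([parse_month(m) for m in t["residuals_log"]], freq="M"),
        ),
        trend=t["trend"],
    )
    c = doc["composition"]
    months = pd.PeriodIndex([parse_month(m) for m in c["residuals_ilr"]], freq="M")
    resid = np.asarray(list(c["residuals_ilr"].values()), dtype=float)
    comp_fit = CompositionModelFit(
        beta0=np.asarray(c["beta0"], dtype=float),
        beta_trend=np.asarray(c["beta_trend"], dtype=float),
        month_effects=np.asarray(c["month_effects"], dtype=float),
        basis=IlrBasis(np.asarray(c["basis"]["matrix"]), label=c["basis"]["label"]),
        categories=tuple(c["categories"]),
        origin=parse_month(c["origin"]),
        window=tuple(parse_month(m) for m in c["window"]),
        residuals_ilr=pd.DataFrame(
            resid, index=months, columns=[f"ilr{i+1}" for i in range(resid.shape[1])]
        ),
        trend=c["trend"],
    )
    return total_fit, comp_fit
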