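"""Synthetic monthly receipts panels with known ground truth.

The generator draws from exactly the model family the estimators assume:
log total receipts follow a linear trend plus month-of-year effects, the
beverage composition follows linear-plus-seasonal trends in ILR coordinates,
and a stacked [log-total, ILR] noise vector is sampled from a multivariate
normal each month. Post-2020 shocks — lockdown dips and rebounds, sustained
cost-of-living deficits, a single-month forestalling spike — are injected on
top, multiplicatively on the revenue scale by default so receipts stay
positive.

Default magnitudes echo the scale of the published UK series (totals near
£1,000m per month in constant prices; shares near beer 0.35, wine 0.35,
spirits 0.25, cider 0.05; ~5% monthly log-scale noise on the total). They
are illustrative study conditions, not estimates.

The generator returns both the observed panel and the *shock-free,
noise-free* expected path, so recovery of injected shocks and calibration of
intervals can be judged against a known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .composition import IlrBasis, helmert_basis, ilr_inverse, ilr_transform
from .data_io import DEFAULT_CATEGORIES, ReceiptsTable, parse_month
from .errors import DomainError, ValidationError
from .models import ExpectedReceipts
from .uncertainty import _psd_factor

__all__ = ["Shock", "GeneratorSpec", "generate", "scenario", "SCENARIOS"]


@dataclass(frozen=True)
class Shock:
    """A deterministic disturbance applied to one series over a month range.

    ``mode='log'`` multiplies the targeted receipts by exp(effect);
    ``mode='additive'`` adds ``effect`` £m (total shocks are spread across
    categories proportionally so coherency is preserved). ``ramp=True``
    scales the effect linearly from 0 at ``start`` up to its full value at
    ``end`` (a gradually deepening shock).
    """

    series: str  # 'total' or a category name
    start: pd.Period
    end: pd.Period
    effect: float
    mode: str = "log"
    ramp: bool = False

    def weights(self, months: pd.PeriodIndex) -> np.ndarray:
        """Per-month multiplier of ``effect`` (0 outside the range)."""
        w = np.zeros(len(months))
        inside = (months >= self.start) & (months <= self.end)
        if self.ramp:
            span = max((self.end - self.start).n, 1)
            w[inside] = np.asarray(
                [(m - self.start).n / span for m in months[inside]]
            )
        else:
            w[inside] = 1.0
        return w


def _seasonal(amplitude: float, peak_month: int = 12) -> np.ndarray:
    """Smooth 12-month effect pattern, zero in January, peaking near Dec."""
    moy = np.arange(1, 13)
    eff = amplitude * np.cos(2 * np.pi * (moy - peak_month) / 12)
    return eff - eff[0]  # January reference = 0


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic data-generating process."""

    start: pd.Period = field(default_factory=lambda: parse_month("2010-01"))
    end: pd.Period = field(default_factory=lambda: parse_month("2025-01"))
    categories: tuple[str, ...] = DEFAULT_CATEGORIES
    beta0: float = float(np.log(950.0))  # log £m at the origin, January
    beta1: float = 0.0015  # ~1.8%/year real growth
    month_effects: np.ndarray = field(
        default_factory=lambda: _seasonal(0.12, peak_month=12)
    )
    base_shares: tuple[float, ...] = (0.35, 0.05, 0.25, 0.35)
    comp_beta1: np.ndarray = field(
        default_factory=lambda: np.array([4e-5, -6e-5, 8e-5])
    )
    comp_month_amplitude: float = 0.02
    noise_sd: np.ndarray = field(
        default_factory=lambda: np.array([0.05, 0.015, 0.015, 0.015])
    )
    noise_corr: float = 0.2  # common off-diagonal correlation
    shocks: tuple[Shock, ...] = ()
    seed: int = 0

    @property
    def months(self) -> pd.PeriodIndex:
        return pd.period_range(self.start, self.end, freq="M")

    @property
    def n_parts(self) -> int:
        return len(self.categories)

    def basis(self) -> IlrBasis:
        return helmert_basis(self.n_parts)

    def comp_beta0(self) -> np.ndarray:
        return ilr_transform(np.asarray(self.base_shares), self.basis())

    def comp_month_effects(self) -> np.ndarray:
        """(D-1, 12) mild seasonal composition swings, January = 0."""
        d1 = self.n_parts - 1
        out = np.zeros((d1, 12))
        for j in range(d1):
            out[j] = _seasonal(self.comp_month_amplitude / (j + 1), peak_month=6 + 2 * j)
        return out

    def noise_cov(self) -> np.ndarray:
        d = self.n_parts
        sd = np.asarray(self.noise_sd, dtype=float)
        if sd.shape != (d,):
            raise DomainError(f"noise_sd must have length {d}")
        corr = np.full((d, d), self.noise_corr)
        np.fill_diagonal(corr, 1.0)
        return corr * np.outer(sd, sd)


def _linear_predictors(spec: GeneratorSpec):
    months = spec.months
    t = np.arange(len(months), dtype=float)
    moy = np.asarray([m.month for m in months])
    log_total = spec.beta0 + spec.beta1 * t + np.asarray(spec.month_effects)[moy - 1]
    z = (
        spec.comp_beta0()[None, :]
        + t[:, None] * np.asarray(spec.comp_beta1)[None, :]
        + spec.comp_month_effects()[:, moy - 1].T
    )
    return months, log_total, z


def generate(spec: GeneratorSpec) -> tuple[ReceiptsTable, ExpectedReceipts]:
    """Draw one synthetic panel; return (observed table, shock-free truth)."""
    months, log_total, z = _linear_predictors(spec)
    basis = spec.basis()
    rng = np.random.default_rng(spec.seed)
    eps = rng.standard_normal((len(months), spec.n_parts)) @ _psd_factor(spec.noise_cov()).T

    total = np.exp(log_total + eps[:, 0])
    shares = ilr_inverse(z + eps[:, 1:], basis)
    if shares.min() < 1e-12:
        raise ValidationError("generator spec drives a share below 1e-12")
    values = total[:, None] * shares

    for shock in spec.shocks:
        w = shock.weights(months)
        if shock.series == "total":
            cols = slice(None)
        elif shock.series in spec.categories:
            cols = [spec.categories.index(shock.series)]
        else:
            raise ValidationError(f"unknown shock series {shock.series!r}")
        if shock.mode == "log":
            values[:, cols] *= np.exp(shock.effect * w)[:, None]
        elif shock.mode == "additive":
            block = values[:, cols]
            add = (shock.effect * w)[:, None] * block / block.sum(axis=1, keepdims=True)
            values[:, cols] = block + add
            if (values[:, cols] <= 0).any():
                raise ValidationError(
                    f"additive shock on {shock.series!r} drives receipts non-positive"
                )
        else:
            raise ValidationError(f"unknown shock mode {shock.mode!r}")

    observed = ReceiptsTable(
        pd.DataFrame(values, index=months, columns=list(spec.categories)),
        basis="deflated(2025-01)",
    )

    truth_total = pd.Series(np.exp(log_total), index=months)
    truth_shares = pd.DataFrame(
        ilr_inverse(z, basis), index=months, columns=list(spec.categories)
    )
    truth = ExpectedReceipts(
        total=truth_total,
        per_category=truth_shares.mul(truth_total, axis=0),
        shares=truth_shares,
        basis_label=basis.label,
        window=(months[0], months[-1]),
    )
    return observed, truth


SCENARIOS = ("null", "lockdown", "cost_of_living", "forestalling")


def scenario(name: str, seed: int = 0, **overrides) -> GeneratorSpec:
    """Preset generator specs mirroring the post-2020 phenomena of interest.

    * ``null`` — no shocks (calibration runs).
    * ``lockdown`` — sharp total dips in spring 2020 and winter 2020/21,
      each followed by a partial rebound as restrictions lift.
    * ``cost_of_living`` — a gradually deepening wine deficit from early
      2022 and a step deficit in spirits from November 2022.
    * ``forestalling`` — a single-month positive spike in August 2023
      (duty cleared early ahead of a rate rise) with an offsetting dip in
      the following two months.
    """
    m = parse_month
    presets: dict[str, tuple[Shock, ...]] = {
        "null": (),
        "lockdown": (
            Shock("total", m("2020-03"), m("2020-04"), -0.35),
            Shock("total", m("2020-06"), m("2020-09"), 0.12),
            Shock("total", m("2020-11"), m("2021-02"), -0.18),
            Shock("total", m("2021-04"), m("2021-07"), 0.08),
        ),
        "cost_of_living": (
            Shock("wine", m("2022-01"), m("2022-12"), -0.30, ramp=True),
            Shock("wine", m("2023-01"), m("2025-01"), -0.30),
            Shock("spirits", m("2022-11"), m("2025-01"), -0.22),
        ),
        "forestalling": (
            Shock("total", m("2023-08"), m("2023-08"), 0.30),
            Shock("total", m("2023-09"), m("2023-10"), -0.16),
        ),
    }
    if name not in presets:
        raise ValidationError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    return replace(GeneratorSpec(seed=seed), shocks=presets[name], **overrides)
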