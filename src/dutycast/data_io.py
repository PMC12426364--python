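"""Reading, writing, validating and deflating monthly receipts panels.

The central container is :class:`ReceiptsTable`: a consecutive monthly panel
of duty receipts in £ million for a fixed, ordered set of beverage
categories. Values may be nominal or expressed in the prices of a reference
month (deflated with a retail price index). Both long
(month, category, value) and wide (month + one column per category) CSV
dialects are read; the long form is written canonically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    CoverageError,
    DomainError,
    GapError,
    ParseError,
    SchemaError,
)

__all__ = [
    "DEFAULT_CATEGORIES",
    "ReceiptsTable",
    "PriceIndexSeries",
    "ReceiptsSchema",
    "parse_month",
    "read_receipts",
    "write_receipts",
    "read_price_index",
    "deflate",
]

DEFAULT_CATEGORIES: tuple[str, ...] = ("beer", "cider", "spirits", "wine")

_MONTH_FORMATS = ("%Y-%m", "%b-%Y", "%B-%Y", "%Y-%m-%d")


def parse_month(value) -> pd.Period:
    """Parse a calendar month from 'YYYY-MM' or 'MMM-YYYY' (normalised)."""
    if isinstance(value, pd.Period):
        return value.asfreq("M")
    s = str(value).strip()
    for fmt in _MONTH_FORMATS:
        try:
            return pd.Period(pd.to_datetime(s, format=fmt), freq="M")
        except ValueError:
            continue
    raise ParseError(f"cannot parse calendar month from {value!r}")


def month_range(first: pd.Period, last: pd.Period) -> pd.PeriodIndex:
    """Inclusive consecutive monthly index from ``first`` to ``last``."""
    if last < first:
        raise DomainError(f"month range is empty: {first}..{last}")
    return pd.period_range(first, last, freq="M")


@dataclass(frozen=True)
class ReceiptsTable:
    """Monthly receipts by category, £ million.

    ``values`` is a DataFrame with a consecutive monthly PeriodIndex and one
    column per category, in a fixed recorded order. ``basis`` is ``nominal``
    or ``deflated(<reference month>)``.
    """

    values: pd.DataFrame
    basis: str = "nominal"

    def __post_init__(self) -> None:
        df = self.values
        if not isinstance(df.index, pd.PeriodIndex) or df.index.freqstr not in ("M",):
            raise SchemaError("ReceiptsTable index must be a monthly PeriodIndex")
        expected = pd.period_range(df.index[0], df.index[-1], freq="M")
        missing = expected.difference(df.index)
        if len(missing):
            raise GapError(f"missing months: {list(missing.astype(str))}")
        if not df.index.equals(expected):
            object.__setattr__(self, "values", df.reindex(expected))
        if df.isna().any().any():
            na = df.isna()
            cells = [
                f"({df.index[i]}, {df.columns[j]})"
                for i, j in zip(*np.nonzero(na.to_numpy()))
            ]
            raise GapError(f"missing cells: {cells}")
        if (df.to_numpy() <= 0).any():
            bad = df[(df <= 0).any(axis=1)].index[0]
            raise DomainError(
                f"non-positive receipts at {bad}; duty refunds are not supported "
                "by the log/ILR models (use floor_epsilon to clip, logged loudly)"
            )

    @property
    def months(self) -> pd.PeriodIndex:
        return self.values.index

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    def total(self) -> pd.Series:
        """Total receipts per month (sum over categories)."""
        return self.values.sum(axis=1)

    def window(self, first=None, last=None) -> "ReceiptsTable":
        """Restrict to an inclusive month range."""
        first = self.months[0] if first is None else parse_month(first)
        last = self.months[-1] if last is None else parse_month(last)
        if first < self.months[0] or last > self.months[-1]:
            raise CoverageError(
                f"window {first}..{last} outside available {self.months[0]}.."
                f"{self.months[-1]}"
            )
        return ReceiptsTable(self.values.loc[first:last], basis=self.basis)

    def shares(self) -> np.ndarray:
        """Per-month composition vectors (rows sum to 1)."""
        v = self.values.to_numpy()
        return v / v.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class PriceIndexSeries:
    """Monthly price index (RPI-style), arbitrary base."""

    index: pd.Series

    def __post_init__(self) -> None:
        s = self.index
        if not isinstance(s.index, pd.PeriodIndex):
            raise SchemaError("PriceIndexSeries needs a monthly PeriodIndex")
        if s.isna().any() or (s <= 0).any():
            raise DomainError("price index values must be strictly positive")

    def factor(self, months: pd.PeriodIndex, reference: pd.Period) -> pd.Series:
        """Deflation factor index(reference)/index(month) for each month."""
        missing = months.difference(self.index.index)
        if len(missing):
            raise CoverageError(
                f"price index missing months: {list(missing.astype(str))}"
            )
        if reference not in self.index.index:
            raise CoverageError(f"reference month {reference} absent from index")
        return float(self.index[reference]) / self.index[months]


@dataclass(frozen=True)
class ReceiptsSchema:
    """Column mapping for receipts CSVs.

    ``layout='long'`` expects (month, category, value) columns;
    ``layout='wide'`` expects a month column plus one column per category;
    ``layout='auto'`` sniffs: long if the category column is present.
    """

    month: str = "month"
    category: str = "category"
    value: str = "value"
    layout: str = "auto"
    categories: Sequence[str] | None = None


def _read_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # noqa: BLE001 - rewrap with context
        raise ParseError(f"cannot parse {path}: {exc}") from exc


def read_receipts(
    path,
    schema: ReceiptsSchema | None = None,
    floor_epsilon: float | None = None,
) -> ReceiptsTable:
    """Read a receipts panel from a long or wide delimited text file.

    ``floor_epsilon`` optionally clips non-positive cells up to that value
    before validation (the log/ILR pipeline is undefined at zero); every clip
    is reported through :mod:`warnings`.
    """
    schema = schema or ReceiptsSchema()
    df = _read_table(path)
    if schema.month not in df.columns:
        raise SchemaError(f"month column {schema.month!r} not in {list(df.columns)}")
    layout = schema.layout
    if layout == "auto":
        layout = "long" if schema.category in df.columns else "wide"

    if layout == "long":
        for col in (schema.category, schema.value):
            if col not in df.columns:
                raise SchemaError(f"column {col!r} missing from long table")
        cats = tuple(schema.categories or DEFAULT_CATEGORIES)
        unknown = set(df[schema.category].unique()) - set(cats)
        if unknown:
            raise SchemaError(f"unknown categories {sorted(unknown)}; expected {cats}")
        months = df[schema.month].map(parse_month)
        values = _numeric(df[schema.value], schema.value)
        wide = pd.DataFrame(
            {"month": months, "category": df[schema.category], "value": values}
        ).pivot(index="month", columns="category", values="value")
        missing_cats = set(cats) - set(wide.columns)
        if missing_cats:
            raise SchemaError(f"categories absent from table: {sorted(missing_cats)}")
        wide = wide[list(cats)]
        na = wide.isna()
        if na.any().any():
            cells = [
                f"({wide.index[i]}, {wide.columns[j]})"
                for i, j in zip(*np.nonzero(na.to_numpy()))
            ]
            raise GapError(f"missing cells: {cells}")
    else:
        cats = tuple(
            schema.categories
            or [c for c in df.columns if c != schema.month and c != "basis"]
        )
        missing_cats = set(cats) - set(df.columns)
        if missing_cats:
            raise SchemaError(f"categories absent from table: {sorted(missing_cats)}")
        wide = pd.DataFrame(
            {c: _numeric(df[c], c).to_numpy() for c in cats},
            index=pd.PeriodIndex(df[schema.month].map(parse_month), freq="M"),
        )

    wide.index.name = "month"
    wide.columns.name = None
    wide = wide.sort_index()
    basis = "nominal"
    if "basis" in df.columns:
        uniq = df["basis"].unique()
        if len(uniq) == 1:
            basis = str(uniq[0])
    if floor_epsilon is not None:
        low = wide < floor_epsilon
        if low.any().any():
            warnings.warn(
                f"flooring {int(low.to_numpy().sum())} non-positive/low cells at "
                f"{floor_epsilon} (log/ILR undefined at 0)",
                stacklevel=2,
            )
            wide = wide.clip(lower=floor_epsilon)
    return ReceiptsTable(wide, basis=basis)


def _numeric(col: pd.Series, name: str) -> pd.Series:
    out = pd.to_numeric(col, errors="coerce")
    bad = out.isna() & col.notna()
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0])
        raise ParseError(
            f"non-numeric value {col.iloc[row]!r} in column {name!r} at data row {row}"
        )
    return out


def write_receipts(table: ReceiptsTable, path) -> None:
    """Write the canonical long CSV (month, category, value, basis)."""
    long = (
        table.values.rename_axis("month")
        .reset_index()
        .melt(id_vars="month", var_name="category", value_name="value")
        .sort_values(["month", "category"], kind="stable")
    )
    long["month"] = long["month"].astype(str)
    long["basis"] = table.basis
    long.to_csv(path, index=False, float_format="%.10g")


def read_price_index(path, month_col: str = "month", value_col: str = "index") -> PriceIndexSeries:
    """Read a (month, index) series from a delimited text file."""
    df = _read_table(path)
    for col in (month_col, value_col):
        if col not in df.columns:
            raise SchemaError(f"column {col!r} not in {list(df.columns)}")
    s = pd.Series(
        _numeric(df[value_col], value_col).to_numpy(),
        index=pd.PeriodIndex(df[month_col].map(parse_month), freq="M"),
    ).sort_index()
    return PriceIndexSeries(s)


def deflate(
    receipts: ReceiptsTable, index: PriceIndexSeries, reference
) -> ReceiptsTable:
    """Express nominal receipts in the prices of ``reference``.

    Each cell is multiplied by index(reference)/index(month); categories and
    ordering are unchanged and totals commute with the operation.
    """
    reference = parse_month(reference)
    if receipts.basis != "nominal":
        raise DomainError(f"receipts already {receipts.basis}; expected nominal")
    f = index.factor(receipts.months, reference)
    out = receipts.values.mul(f.to_numpy(), axis=0)
    return ReceiptsTable(out, basis=f"deflated({reference})")
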