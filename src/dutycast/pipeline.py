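"""End-to-end analysis runner driven by a declarative config.

``run(config)`` executes fit → forecast → bootstrap → deviations →
coverage → figures and writes a reproducible bundle: fitted coefficients
(JSON), expected receipts and deviation tables (CSV), the training-period
interval-coverage table, figures, a machine-readable run manifest and a
plain-text log. Identical config and seed give byte-identical CSV output.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .composition import IlrBasis, helmert_basis
from .data_io import ReceiptsTable, deflate, read_price_index, read_receipts
from .deviation import analyse, run_sensitivity
from .errors import ValidationError
from .models import fits_to_json
from .uncertainty import coverage_check, prediction_intervals

__all__ = ["AnalysisConfig", "run"]


@dataclass
class AnalysisConfig:
    """Declarative description of one full analysis run."""

    receipts_path: str
    output_dir: str
    seed: int
    price_index_path: str | None = None
    reference_month: str = "2025-01"
    training_start: str | None = None
    training_end: str = "2019-12"
    forecast_end: str | None = None
    deviation_start: str | None = None
    ilr_basis: str = "helmert"  # 'helmert' or path to a CSV contrast matrix
    trend: str = "linear"
    n_draws: int = 10_000
    level: float = 0.95
    draw_method: str = "parametric"
    sensitivity_cutoffs: list[str] = field(default_factory=list)
    floor_epsilon: float | None = None
    make_figures: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.level < 1:
            raise ValidationError(f"level must be in (0,1), got {self.level}")
        if self.n_draws < 1:
            raise ValidationError("n_draws must be >= 1")
        if self.seed is None:
            raise ValidationError("seed is mandatory for reproducible runs")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def resolve_basis(self, n_parts: int) -> IlrBasis:
        if self.ilr_basis == "helmert":
            return helmert_basis(n_parts)
        matrix = np.loadtxt(self.ilr_basis, delimiter=",")
        return IlrBasis(np.atleast_2d(matrix), label=f"custom:{self.ilr_basis}")


def _config_hash(config: AnalysisConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_inputs(config: AnalysisConfig) -> ReceiptsTable:
    """Read receipts and, if a price index is configured, deflate them."""
    receipts = read_receipts(config.receipts_path, floor_epsilon=config.floor_epsilon)
    if config.price_index_path:
        index = read_price_index(config.price_index_path)
        receipts = deflate(receipts, index, config.reference_month)
    return receipts


def run(config: AnalysisConfig) -> dict:
    """Execute the full pipeline; return a manifest of output paths."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"dutycast {__version__} run, config hash {_config_hash(config)}"]

    receipts = load_inputs(config)
    log_lines.append(
        f"loaded {len(receipts.months)} months x {len(receipts.categories)} "
        f"categories ({receipts.basis})"
    )
    basis = config.resolve_basis(len(receipts.categories))

    total_fit, comp_fit, expected, draws, report = analyse(
        receipts,
        training_end=config.training_end,
        training_start=config.training_start,
        forecast_end=config.forecast_end,
        deviation_start=config.deviation_start,
        basis=basis,
        trend=config.trend,
        n_draws=config.n_draws,
        level=config.level,
        seed=config.seed,
        method=config.draw_method,
    )
    log_lines.append(
        f"fitted window {total_fit.window[0]}..{total_fit.window[1]}, "
        f"log-trend slope {total_fit.beta1:.6f}/month"
    )

    paths = {}
    paths["fits"] = out / "fits.json"
    fits_to_json(total_fit, comp_fit, paths["fits"])

    exp_frame = expected.per_category.copy()
    exp_frame.insert(0, "total", expected.total)
    exp_frame.index = exp_frame.index.astype(str)
    paths["expected"] = out / "expected.csv"
    exp_frame.rename_axis("month").to_csv(paths["expected"], float_format="%.6f")

    paths["deviations"] = out / "deviations.csv"
    report.to_tidy().to_csv(paths["deviations"], index=False, float_format="%.6f")

    # training-period interval coverage (calibration diagnostic)
    intervals = prediction_intervals(draws, level=config.level)
    coverage = coverage_check(receipts, intervals, window=total_fit.window)
    paths["coverage"] = out / "coverage.csv"
    coverage.rename_axis("series").to_csv(paths["coverage"], float_format="%.4f")
    log_lines.append(f"training coverage (total): {coverage['total']:.3f}")

    # headline accounting
    cum = report.cumulative["point"]["total"].iloc[-1]
    rel = report.relative_cumulative["point"]["total"].iloc[-1]
    log_lines.append(
        f"cumulative deviation since {report.start}: {cum:.1f} £m ({rel:.2f}%)"
    )

    if config.sensitivity_cutoffs:
        sens = run_sensitivity(
            receipts,
            config.sensitivity_cutoffs,
            basis=basis,
            trend=config.trend,
            n_draws=config.n_draws,
            level=config.level,
            seed=config.seed,
            method=config.draw_method,
        )
        for cutoff, rep in sens.items():
            p = out / f"deviations_cutoff_{cutoff}.csv"
            rep.to_tidy().to_csv(p, index=False, float_format="%.6f")
            paths[f"sensitivity:{cutoff}"] = p

    if config.make_figures:
        from .plots import plot_report

        for fig_path in plot_report(report, out):
            paths[fig_path.stem] = fig_path

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "outputs": {k: str(v) for k, v in paths.items()},
        "headline": {
            "cumulative_deviation_gbp_m": float(cum),
            "relative_cumulative_deviation_pct": float(rel),
            "training_coverage_total": float(coverage["total"]),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return manifest
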