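"""Deviation figures: monthly and cumulative, total and by beverage."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .deviation import DeviationReport

__all__ = ["plot_report"]


def _panel(ax, part, name, title):
    months = part["point"].index.to_timestamp()
    ax.axhline(0.0, color="0.4", lw=0.8)
    ax.fill_between(
        months, part["lower"][name], part["upper"][name],
        alpha=0.25, color="tab:blue", label="95% PI",
    )
    ax.plot(months, part["point"][name], color="tab:blue", lw=1.2)
    ax.set_title(title, fontsize=9)
    ax.tick_params(labelsize=7)


def plot_report(report: DeviationReport, out_dir) -> list[Path]:
    """Write monthly/cumulative deviation figures; return their paths."""
    out_dir = Path(out_dir)
    paths = []
    for metric, label in (("monthly", "Monthly deviation (£m)"),
                          ("cumulative", "Cumulative deviation (£m)")):
        part = getattr(report, metric)
        if not part:
            continue

        fig, ax = plt.subplots(figsize=(7, 3.2), constrained_layout=True)
        _panel(ax, part, "total", f"{label}, observed − expected, total")
        p = out_dir / f"fig_{metric}_total.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)

        cats = report.observed.categories
        fig, axes = plt.subplots(
            2, (len(cats) + 1) // 2, figsize=(8, 5), constrained_layout=True
        )
        for ax, cat in zip(axes.ravel(), cats):
            _panel(ax, part, cat, cat)
        for ax in axes.ravel()[len(cats):]:
            ax.axis("off")
        fig.suptitle(f"{label} by beverage type", fontsize=10)
        p = out_dir / f"fig_{metric}_by_category.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths
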