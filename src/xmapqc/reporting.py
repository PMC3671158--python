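"""Curve and QC visualizations.

Figures are built with the matplotlib Figure API (no pyplot state), so
rendering is deterministic and backend-free.  Standard-curve plots show
the fitted logistic over the observed dose range with replicate-group
means overlaid; excluded points are rendered distinctly.  Multi-run
overlays (the curve "graveyard") show one series per run on both FI and
log(FI) panels.  Levey-Jennings charts draw the run series with the
guide-set mean and +/- 1, 2, 3 SD bands.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.backends.backend_pdf import PdfPages
from matplotlib.figure import Figure

from .curves import CurveFit, TitrationPoint, eval_logistic
from .errors import XmapError

__all__ = [
    "standard_curve_figure",
    "plot_standard_curve",
    "overlay_figure",
    "plot_curve_overlay",
    "levey_jennings_figure",
    "save_figure",
    "save_curve_book",
]


def _curve_grid(points: list[TitrationPoint], n: int = 200) -> np.ndarray:
    doses = [p.dose for p in points]
    return np.logspace(np.log10(min(doses)), np.log10(max(doses)), n)


def standard_curve_figure(
    fit: CurveFit,
    points: list[TitrationPoint],
    title: str = "",
) -> Figure:
    """One titration: fitted curve plus observed replicate-group means.

    A non-converged fit yields a points-only plot with a warning
    annotation.
    """
    fig = Figure(figsize=(6, 4.5))
    ax = fig.add_subplot(111)
    used = [p for p in points if not p.excluded]
    excl = [p for p in points if p.excluded]
    if used:
        ax.plot(
            [p.dose for p in used], [p.mean_response for p in used],
            "o", color="tab:blue", label="replicate-group mean",
        )
    if excl:
        ax.plot(
            [p.dose for p in excl], [p.mean_response for p in excl],
            "x", color="tab:red", markersize=9, label="excluded",
        )
    if fit.converged and fit.params is not None and points:
        grid = _curve_grid(points)
        ax.plot(
            grid, eval_logistic(fit.params, grid), "-",
            color="tab:blue", label=f"{fit.model} fit",
        )
    else:
        ax.annotate(
            "fit did not converge", xy=(0.5, 0.5),
            xycoords="axes fraction", ha="center", color="tab:red",
        )
    ax.set_xscale("log")
    ax.set_xlabel("dose (expected concentration)")
    ax.set_ylabel("response (prepared FI)")
    if title:
        ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    return fig


def plot_standard_curve(
    fit: CurveFit,
    points: list[TitrationPoint],
    out_path: Path | str,
    title: str = "",
) -> Path:
    fig = standard_curve_figure(fit, points, title=title)
    return save_figure(fig, out_path)


def overlay_figure(
    fits: list[tuple[str, CurveFit, list[TitrationPoint]]],
    analyte: str = "",
) -> Figure:
    """Curves from several runs of the same analyte/titration on shared
    axes, with FI and log(FI) panels."""
    if not fits:
        raise XmapError("overlay needs at least one fit")
    fig = Figure(figsize=(10, 4.5))
    ax_fi = fig.add_subplot(121)
    ax_log = fig.add_subplot(122)
    for run_label, fit, points in fits:
        if not (fit.converged and fit.params is not None and points):
            continue
        grid = _curve_grid(points)
        y = eval_logistic(fit.params, grid)
        ax_fi.plot(grid, y, label=run_label)
        ax_log.plot(grid, np.log10(np.maximum(y, 1e-9)), label=run_label)
    for ax, ylabel in ((ax_fi, "FI"), (ax_log, "log10(FI)")):
        ax.set_xscale("log")
        ax.set_xlabel("dose")
        ax.set_ylabel(ylabel)
        ax.legend(loc="best", fontsize=7)
    if analyte:
        fig.suptitle(f"{analyte} standard curves")
    return fig


def plot_curve_overlay(
    fits: list[tuple[str, CurveFit, list[TitrationPoint]]],
    out_path: Path | str,
    analyte: str = "",
) -> Path:
    fig = overlay_figure(fits, analyte=analyte)
    return save_figure(fig, out_path)


def levey_jennings_figure(
    series: pd.DataFrame, title: str = ""
) -> Figure:
    """Run-ordered metric values with guide-set mean and SD bands."""
    fig = Figure(figsize=(8, 4.5))
    ax = fig.add_subplot(111)
    x = np.arange(len(series))
    band_colors = {1: "#c8e6c9", 2: "#fff9c4", 3: "#ffcdd2"}
    for k in (3, 2, 1):
        lo = series[f"band{k}_lo"].to_numpy(dtype=float)
        hi = series[f"band{k}_hi"].to_numpy(dtype=float)
        ax.fill_between(
            x, lo, hi, where=~np.isnan(lo), color=band_colors[k],
            label=f"±{k} SD",
        )
    ax.plot(x, series["mu"].to_numpy(dtype=float), "--", color="gray",
            linewidth=1, label="guide-set mean")
    values = series["value"].to_numpy(dtype=float)
    ax.plot(x, values, "o-", color="tab:blue", markersize=4)
    flagged = series["flagged"].to_numpy(dtype=bool)
    if flagged.any():
        ax.plot(x[flagged], values[flagged], "o", color="tab:red",
                markersize=8, fillstyle="none", label="flagged")
    ax.set_xticks(x)
    ax.set_xticklabels(series["run_id"], rotation=45, ha="right",
                       fontsize=7)
    ax.set_ylabel(series["metric"].iloc[0] if len(series) else "metric")
    if title:
        ax.set_title(title)
    ax.legend(loc="best", fontsize=7)
    fig.tight_layout()
    return fig


def save_figure(fig: Figure, out_path: Path | str) -> Path:
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    FigureCanvasAgg(fig)
    fig.savefig(out_path, dpi=120)
    return out_path


def save_curve_book(
    figures: list[Figure], out_path: Path | str
) -> Path:
    """Bundle all of a run's titration-curve plots into one PDF."""
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    with PdfPages(out_path) as pdf:
        for fig in figures:
            FigureCanvasAgg(fig)
            pdf.savefig(fig)
    return out_path
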