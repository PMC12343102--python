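"""Publication-style panels: correlation grid, rank curves, ROC, ORA bars.

Plotting only renders already-computed result objects; no statistics are
recomputed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .core import EnrichmentCurve
from .enrich import OraResult
from .io_tables import RatioTable
from .qc import CorrelationMatrix

__all__ = [
    "PlotSpec",
    "render",
    "plot_correlation_grid",
    "plot_enrichment_curves",
    "plot_roc",
    "plot_ora_bars",
]

# series colors for the rank-scan panel
TPR_COLOR = "tab:blue"
FPR_COLOR = "tab:orange"
DIFF_COLOR = "tab:green"


@dataclass
class PlotSpec:
    kind: Literal["correlation_grid", "enrichment_curves", "roc", "ora_bars"]
    source: object
    path: str | Path
    image_format: Literal["png", "svg", "pdf"] = "png"
    dpi: int = 150


def _save(fig: plt.Figure, path: str | Path, fmt: str, dpi: int) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    kwargs = {}
    if fmt == "svg":
        # deterministic vector output: fixed hash salt, no timestamp
        plt.rcParams["svg.hashsalt"] = "proxifilter"
        kwargs["metadata"] = {"Date": None}
    fig.savefig(path, format=fmt, dpi=dpi, **kwargs)
    plt.close(fig)
    return path


def plot_enrichment_curves(
    curve: EnrichmentCurve, path: str | Path, fmt: str = "png", dpi: int = 150
) -> Path:
    """TPR, FPR and TPR-FPR against rank, with the cutoff marked."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ranks = np.arange(1, len(curve.accessions) + 1)
    ax.plot(ranks, curve.tpr, color=TPR_COLOR, label="TPR")
    ax.plot(ranks, curve.fpr, color=FPR_COLOR, label="FPR")
    ax.plot(ranks, curve.diff, color=DIFF_COLOR, label="TPR − FPR")
    ax.axvline(curve.cutoff_rank, color="red", ls="--", lw=0.8)
    ax.set_xlabel("ratio-based rank")
    ax.set_ylabel("rate")
    ax.set_title(f"{curve.column_name} (cutoff rank {curve.cutoff_rank})")
    ax.legend(frameon=False)
    fig.tight_layout()
    return _save(fig, path, fmt, dpi)


def plot_roc(
    curve: EnrichmentCurve, path: str | Path, fmt: str = "png", dpi: int = 150
) -> Path:
    """ROC step curve with diagonal, AUC annotation, and cutoff marker."""
    fig, ax = plt.subplots(figsize=(4.2, 4))
    pts = curve.roc_points
    ax.plot(pts[:, 0], pts[:, 1], color=TPR_COLOR)
    ax.plot([0, 1], [0, 1], color="grey", ls=":", lw=0.8)
    k = curve.cutoff_rank - 1
    ax.plot(curve.fpr[k], curve.tpr[k], "o", color="red", zorder=5)
    ax.annotate(f"AUC = {curve.auc:.2f}", xy=(0.55, 0.1), xycoords="axes fraction")
    ax.set_xlabel("FPR")
    ax.set_ylabel("TPR")
    ax.set_title(curve.column_name)
    fig.tight_layout()
    return _save(fig, path, fmt, dpi)


def plot_correlation_grid(
    table: RatioTable,
    corr: CorrelationMatrix,
    path: str | Path,
    fmt: str = "png",
    dpi: int = 150,
) -> Path:
    """Pairwise log2 scatter grid with the correlation coefficient annotated."""
    cols = corr.column_names
    k = len(cols)
    fig, axes = plt.subplots(k, k, figsize=(2.2 * k, 2.2 * k), squeeze=False)
    log_data = np.log2(table.data[cols])
    for i, ci in enumerate(cols):
        for j, cj in enumerate(cols):
            ax = axes[i][j]
            if i == j:
                ax.hist(log_data[ci].dropna(), bins=30, color=TPR_COLOR)
            else:
                ax.scatter(log_data[cj], log_data[ci], s=2, alpha=0.3, color=TPR_COLOR)
                r = corr.coefficients.loc[ci, cj]
                label = "r = n/a" if np.isnan(r) else f"r = {r:.2f}"
                ax.annotate(label, xy=(0.05, 0.88), xycoords="axes fraction", fontsize=8)
            if i == k - 1:
                ax.set_xlabel(cj, fontsize=8)
            if j == 0:
                ax.set_ylabel(ci, fontsize=8)
            ax.tick_params(labelsize=6)
    fig.suptitle(f"pairwise correlation ({corr.method})", fontsize=10)
    fig.tight_layout()
    return _save(fig, path, fmt, dpi)


def plot_ora_bars(
    result: OraResult,
    path: str | Path,
    top: int = 10,
    fmt: str = "png",
    dpi: int = 150,
) -> Path:
    """Most significant terms as horizontal fold-enrichment bars."""
    table = result.table.head(top)
    fig, ax = plt.subplots(figsize=(6, 0.45 * max(len(table), 2) + 1))
    if len(table):
        ypos = np.arange(len(table))[::-1]
        ax.barh(ypos, table["fold_enrichment"], color=TPR_COLOR)
        ax.set_yticks(ypos, table["name"], fontsize=8)
        for y, (_, row) in zip(ypos, table.iterrows()):
            ax.annotate(
                f"FDR = {row['fdr']:.2g}",
                xy=(row["fold_enrichment"], y),
                xytext=(3, -3),
                textcoords="offset points",
                fontsize=7,
            )
    ax.set_xlabel("fold enrichment")
    fig.tight_layout()
    return _save(fig, path, fmt, dpi)


def render(spec: PlotSpec) -> Path:
    """Dispatch a :class:`PlotSpec` to the matching plot function."""
    if spec.kind == "enrichment_curves":
        return plot_enrichment_curves(spec.source, spec.path, spec.image_format, spec.dpi)
    if spec.kind == "roc":
        return plot_roc(spec.source, spec.path, spec.image_format, spec.dpi)
    if spec.kind == "correlation_grid":
        table, corr = spec.source
        return plot_correlation_grid(table, corr, spec.path, spec.image_format, spec.dpi)
    if spec.kind == "ora_bars":
        return plot_ora_bars(spec.source, spec.path, fmt=spec.image_format, dpi=spec.dpi)
    raise ValueError(f"unknown plot kind: {spec.kind!r}")
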