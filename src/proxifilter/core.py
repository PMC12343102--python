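"""Ranked-ratio reference scan: TPR/FPR curves, ROC/AUC, cutoff, intersection.

The contaminant-removal strategy: rank detected proteins by their
labeled-to-control ratio (descending), scan the list marking curated
true positives and false positives, and cut at the rank where TPR - FPR
peaks. Everything at or above the cutoff is retained regardless of
annotation status; the final proteome is the intersection of the retained
sets across all ratio columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .io_tables import RatioTable, ReferenceSet

logger = logging.getLogger(__name__)

__all__ = [
    "TP",
    "FP",
    "UNANNOTATED",
    "RankedColumn",
    "EnrichmentCurve",
    "CutoffResult",
    "rank_column",
    "compute_curve",
    "find_cutoff",
    "compute_auc",
    "apply_cutoff",
    "intersect",
    "top_enriched",
    "analyze_table",
]

TP = "TP"
FP = "FP"
UNANNOTATED = "UNANNOTATED"

TiePolicy = Literal["last", "first"]


@dataclass
class RankedColumn:
    """One ratio column sorted descending, with reference labels attached."""

    column_name: str
    accessions: np.ndarray  # object dtype, rank order
    ratios: np.ndarray  # float, non-increasing
    labels: np.ndarray  # object dtype, TP / FP / UNANNOTATED

    def __post_init__(self) -> None:
        self.accessions = np.asarray(self.accessions, dtype=object)
        self.ratios = np.asarray(self.ratios, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if not (len(self.accessions) == len(self.ratios) == len(self.labels)):
            raise ValueError("ranked column arrays must have equal length")
        if len(self.ratios) and np.any(np.diff(self.ratios) > 0):
            raise ValueError("ratios must be non-increasing down the ranking")
        if self.n_tp < 1 or self.n_fp < 1:
            raise AnalysisError(
                f"column {self.column_name!r}: reference does not overlap data "
                f"(n_tp={self.n_tp}, n_fp={self.n_fp})"
            )

    @property
    def n_tp(self) -> int:
        return int(np.sum(self.labels == TP))

    @property
    def n_fp(self) -> int:
        return int(np.sum(self.labels == FP))

    def __len__(self) -> int:
        return len(self.accessions)


@dataclass
class EnrichmentCurve:
    """Per-rank TPR/FPR/(TPR-FPR) arrays plus ROC points, AUC and cutoff rank."""

    column_name: str
    accessions: np.ndarray
    ratios: np.ndarray
    labels: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    diff: np.ndarray
    cutoff_rank: int  # 1-based
    auc: float
    roc_points: np.ndarray  # shape (m, 2): (fpr, tpr), from (0,0) to (1,1)

    def to_frame(self) -> pd.DataFrame:
        """Curve table: rank, accession, ratio, label, tpr, fpr, diff."""
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.accessions) + 1),
                "accession": self.accessions,
                "ratio": self.ratios,
                "label": self.labels,
                "tpr": self.tpr,
                "fpr": self.fpr,
                "diff": self.diff,
            }
        )


@dataclass
class CutoffResult:
    """Per-column retained sets and their intersection (the final proteome)."""

    per_column_retained: dict[str, frozenset[str]]
    final_proteome: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        sets = list(self.per_column_retained.values())
        if not sets:
            raise ValueError("need at least one column")
        self.final_proteome = frozenset(frozenset.intersection(*sets))


def rank_column(table: RatioTable, column: str, ref: ReferenceSet) -> RankedColumn:
    """Sort one column descending (stable for ties) and attach TP/FP labels.

    Cells flagged missing in this column are excluded. Raises
    :class:`~proxifilter.errors.AnalysisError` if no TP or no FP remains.
    """
    if column not in table.ratio_columns:
        raise KeyError(f"no such ratio column: {column!r}")
    series = table.column_values(column)
    values = series.to_numpy(dtype=float)
    # stable argsort on negated values: ties keep input-row order
    order = np.argsort(-values, kind="stable")
    accs = series.index.to_numpy(dtype=object)[order]
    labels = np.array(
        [TP if a in ref.tp else FP if a in ref.fp else UNANNOTATED for a in accs],
        dtype=object,
    )
    return RankedColumn(column, accs, values[order], labels)


def find_cutoff(diff: Sequence[float], tie_policy: TiePolicy = "last") -> int:
    """1-based rank maximizing TPR - FPR.

    When the maximum is attained at several ranks, ``tie_policy='last'``
    (default) returns the deepest such rank — retaining more proteins at
    identical criterion value — and ``'first'`` the shallowest.
    """
    arr = np.asarray(diff, dtype=float)
    if arr.size == 0:
        raise ValueError("empty diff sequence")
    hits = np.flatnonzero(arr == arr.max())
    idx = hits[-1] if tie_policy == "last" else hits[0]
    return int(idx) + 1


def compute_auc(ranked: RankedColumn) -> tuple[float, np.ndarray]:
    """Trapezoidal area under the ROC step curve, tie-blocked.

    Entries sharing an identical ratio value are processed as a single
    block (one ROC segment), making the result independent of tie order
    and equal to the Mann-Whitney probability
    ``P(ratio_TP > ratio_FP) + 0.5 * P(ratio_TP == ratio_FP)``.

    Returns ``(auc, roc_points)`` with roc_points running from (0, 0)
    to (1, 1) as (fpr, tpr) pairs.
    """
    is_tp = ranked.labels == TP
    is_fp = ranked.labels == FP
    # block boundaries: positions where the ratio changes
    change = np.flatnonzero(np.diff(ranked.ratios) != 0)
    ends = np.concatenate([change, [len(ranked) - 1]])  # inclusive block ends
    tp_cum = np.cumsum(is_tp)[ends] / ranked.n_tp
    fp_cum = np.cumsum(is_fp)[ends] / ranked.n_fp
    fpr = np.concatenate([[0.0], fp_cum])
    tpr = np.concatenate([[0.0], tp_cum])
    auc = float(np.trapezoid(tpr, fpr))
    return auc, np.column_stack([fpr, tpr])


def compute_curve(ranked: RankedColumn, tie_policy: TiePolicy = "last") -> EnrichmentCurve:
    """Cumulative TPR/FPR/(TPR-FPR) per rank, plus ROC/AUC and cutoff rank."""
    is_tp = ranked.labels == TP
    is_fp = ranked.labels == FP
    tpr = np.cumsum(is_tp) / ranked.n_tp
    fpr = np.cumsum(is_fp) / ranked.n_fp
    diff = tpr - fpr
    cutoff = find_cutoff(diff, tie_policy)
    auc, roc_points = compute_auc(ranked)
    return EnrichmentCurve(
        column_name=ranked.column_name,
        accessions=ranked.accessions,
        ratios=ranked.ratios,
        labels=ranked.labels,
        tpr=tpr,
        fpr=fpr,
        diff=diff,
        cutoff_rank=cutoff,
        auc=auc,
        roc_points=roc_points,
    )


def apply_cutoff(ranked: RankedColumn, cutoff_rank: int) -> frozenset[str]:
    """Accessions at ranks 1..cutoff_rank inclusive (unannotated ones too)."""
    if not 1 <= cutoff_rank <= len(ranked):
        raise ValueError(
            f"cutoff rank {cutoff_rank} out of range 1..{len(ranked)}"
        )
    return frozenset(ranked.accessions[:cutoff_rank])


def intersect(per_column_retained: Mapping[str, Iterable[str]]) -> CutoffResult:
    """Final proteome = proteins that passed the cutoff in every column."""
    result = CutoffResult(
        {name: frozenset(accs) for name, accs in per_column_retained.items()}
    )
    if not result.final_proteome:
        logger.warning("final proteome is empty: per-column retained sets are disjoint")
    return result


def top_enriched(ranked: RankedColumn, n: int = 100) -> pd.DataFrame:
    """First ``min(n, len(ranked))`` entries as a (rank, accession, ratio) table."""
    if n < 1:
        raise ValueError("n must be >= 1")
    m = min(n, len(ranked))
    return pd.DataFrame(
        {
            "rank": np.arange(1, m + 1),
            "accession": ranked.accessions[:m],
            "ratio": ranked.ratios[:m],
        }
    )


def analyze_table(
    table: RatioTable,
    ref: ReferenceSet,
    columns: Sequence[str] | None = None,
    tie_policy: TiePolicy = "last",
    top_n: int = 100,
) -> tuple[list[EnrichmentCurve], CutoffResult, dict[str, pd.DataFrame]]:
    """Run the per-column scan + cutoff on every requested column and intersect.

    Convenience wrapper used by the CLI; returns the curves, the cutoff
    result, and the per-column top-N tables.
    """
    cols = list(columns) if columns is not None else table.ratio_columns
    curves: list[EnrichmentCurve] = []
    retained: dict[str, frozenset[str]] = {}
    tops: dict[str, pd.DataFrame] = {}
    for col in cols:
        ranked = rank_column(table, col, ref)
        curve = compute_curve(ranked, tie_policy)
        curves.append(curve)
        retained[col] = apply_cutoff(ranked, curve.cutoff_rank)
        tops[col] = top_enriched(ranked, top_n)
    return curves, intersect(retained), tops
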