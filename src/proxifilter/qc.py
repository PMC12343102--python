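"""Replicate-consistency QC: pairwise correlation of ratio columns."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import QCError
from .io_tables import RatioTable

logger = logging.getLogger(__name__)

__all__ = ["CorrelationMatrix", "pairwise_correlation"]

CorrMethod = Literal["pearson_log2", "spearman"]

#: A pair needs at least this many complete observations for a coefficient.
MIN_COMPLETE = 3


@dataclass
class CorrelationMatrix:
    """Symmetric pairwise correlation of ratio columns.

    ``coefficients`` has exact 1.0 on the diagonal; a pair with fewer than
    :data:`MIN_COMPLETE` complete observations is reported as NaN
    (undefined, not fabricated). ``n_complete`` counts the proteins
    non-missing in both columns of each pair.
    """

    column_names: list[str]
    coefficients: pd.DataFrame
    method: CorrMethod
    n_complete: pd.DataFrame


def _pair_corr(x: np.ndarray, y: np.ndarray, method: CorrMethod) -> float:
    if method == "pearson_log2":
        lx, ly = np.log2(x), np.log2(y)
        if np.ptp(lx) == 0 or np.ptp(ly) == 0:
            return float("nan")  # zero variance: undefined
        return float(stats.pearsonr(lx, ly).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown correlation method: {method!r}")


def pairwise_correlation(
    table: RatioTable, method: CorrMethod = "pearson_log2"
) -> CorrelationMatrix:
    """Correlate every pair of ratio columns over pairwise-complete rows.

    ``pearson_log2`` computes Pearson's r on log2-transformed ratios
    (ratios are multiplicative, so log space is where linearity is
    expected); ``spearman`` is rank-based and transform-free.
    """
    cols = table.ratio_columns
    if len(cols) < 2:
        raise QCError("pairwise correlation needs at least 2 ratio columns")
    k = len(cols)
    coef = np.eye(k)
    n_complete = np.zeros((k, k), dtype=int)
    data = table.data
    notna = data.notna().to_numpy()
    values = data.to_numpy(dtype=float)
    for i in range(k):
        n_complete[i, i] = int(notna[:, i].sum())
        for j in range(i + 1, k):
            mask = notna[:, i] & notna[:, j]
            n = int(mask.sum())
            n_complete[i, j] = n_complete[j, i] = n
            if n < MIN_COMPLETE:
                logger.warning(
                    "pair (%s, %s): only %d complete observations; "
                    "correlation undefined",
                    cols[i],
                    cols[j],
                    n,
                )
                r = float("nan")
            else:
                r = _pair_corr(values[mask, i], values[mask, j], method)
            coef[i, j] = coef[j, i] = r
    return CorrelationMatrix(
        column_names=list(cols),
        coefficients=pd.DataFrame(coef, index=cols, columns=cols),
        method=method,
        n_complete=pd.DataFrame(n_complete, index=cols, columns=cols),
    )
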