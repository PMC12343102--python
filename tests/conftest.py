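"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from proxifilter.core import FP, TP, UNANNOTATED, RankedColumn
from proxifilter.io_tables import RatioTable, ReferenceSet

# ---------------------------------------------------------------------------
# independent oracles (never share code with the implementation under test)


def mann_whitney_auc(ratios, labels) -> float:
    """Brute-force pairwise AUC: P(TP > FP) + 0.5 * P(TP == FP)."""
    tp = [r for r, l in zip(ratios, labels) if l == TP]
    fp = [r for r, l in zip(ratios, labels) if l == FP]
    score = 0.0
    for a in tp:
        for b in fp:
            if a > b:
                score += 1.0
            elif a == b:
                score += 0.5
    return score / (len(tp) * len(fp))


def cumulative_rates(labels):
    """Direct enumeration of per-rank TPR/FPR by counting prefixes."""
    n_tp = labels.count(TP)
    n_fp = labels.count(FP)
    tpr, fpr = [], []
    for k in range(1, len(labels) + 1):
        prefix = labels[:k]
        tpr.append(prefix.count(TP) / n_tp)
        fpr.append(prefix.count(FP) / n_fp)
    return tpr, fpr


def hypergeom_tail_exact(N: int, K: int, n: int, k: int) -> Fraction:
    """Exact rational upper-tail hypergeometric probability P(X >= k)."""
    total = comb(N, n)
    acc = Fraction(0)
    for i in range(max(k, 0), min(n, K) + 1):
        acc += Fraction(comb(K, i) * comb(N - K, n - i), total)
    return acc


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def toy_ranked() -> RankedColumn:
    """The canonical 5-protein worked example (distinct descending ratios)."""
    return RankedColumn(
        column_name="R1",
        accessions=np.array(["P1", "P2", "P3", "P4", "P5"], dtype=object),
        ratios=np.array([5.0, 4.0, 3.0, 2.0, 1.0]),
        labels=np.array([TP, FP, TP, UNANNOTATED, FP], dtype=object),
    )


@pytest.fixture
def toy_table() -> RatioTable:
    return RatioTable(
        pd.DataFrame(
            {"R1": [5.0, 4.0, 3.0, 2.0, 1.0]},
            index=pd.Index(["P1", "P2", "P3", "P4", "P5"], name="accession"),
        )
    )


@pytest.fixture
def toy_ref() -> ReferenceSet:
    return ReferenceSet(tp=frozenset({"P1", "P3"}), fp=frozenset({"P2", "P5"}))


def random_ranked(rng: np.random.Generator, max_n: int = 50) -> RankedColumn:
    """Random small instance with ties; guaranteed >=1 TP and >=1 FP."""
    n = int(rng.integers(2, max_n + 1))
    # small value pool forces ties
    ratios = rng.choice([1.0, 2.0, 3.0, 5.0, 8.0], size=n)
    labels = rng.choice([TP, FP, UNANNOTATED], size=n, p=[0.35, 0.35, 0.3])
    labels[0] = TP
    labels[-1] = FP
    order = np.argsort(-ratios, kind="stable")
    return RankedColumn(
        column_name="rand",
        accessions=np.array([f"P{i:04d}" for i in range(n)], dtype=object)[order],
        ratios=ratios[order],
        labels=np.asarray(labels, dtype=object)[order],
    )
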