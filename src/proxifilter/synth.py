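"""Synthetic ratio tables with the statistical structure the method assumes.

Two-component log-normal model: true positives draw a latent log2 ratio
from Normal(mu_tp, sigma), false positives from Normal(mu_fp, sigma),
unannotated rows from a 50:50 mixture of the two; each ratio column adds
independent Normal(0, replicate_sd) noise and ratios are emitted as
2**(latent + noise), hence positive. The ``failed`` mode draws every row
from the contaminant component regardless of label, giving diagonal
TPR/FPR/ROC curves — a negative control for the whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_tables import RatioTable, ReferenceSet

__all__ = ["SynthConfig", "generate", "subsample_reference"]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the two-component log2-ratio simulation."""

    n_tp: int = 500
    n_fp: int = 500
    n_unannotated: int = 0
    mu_tp: float = 2.0
    mu_fp: float = 0.0
    sigma: float = 1.0
    n_columns: int = 1
    replicate_sd: float = 0.0
    failed: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tp < 1 or self.n_fp < 1 or self.n_unannotated < 0:
            raise ValueError("need n_tp >= 1, n_fp >= 1, n_unannotated >= 0")
        if self.sigma <= 0 or self.replicate_sd < 0:
            raise ValueError("need sigma > 0 and replicate_sd >= 0")
        if self.n_columns < 1:
            raise ValueError("need n_columns >= 1")


def generate(config: SynthConfig) -> tuple[RatioTable, ReferenceSet, pd.DataFrame]:
    """Simulate a ratio table plus matching references and a truth table.

    Returns ``(table, reference, truth)`` where ``truth`` records each
    accession's generating group and latent log2 value. Deterministic for
    a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    groups = (
        [("TP", config.n_tp)],
        [("FP", config.n_fp)],
        [("UN", config.n_unannotated)],
    )
    accs: list[str] = []
    labels: list[str] = []
    for part in groups:
        for tag, count in part:
            accs.extend(f"{tag}{i:06d}" for i in range(count))
            labels.extend([tag] * count)
    labels_arr = np.array(labels)
    n = len(accs)

    if config.failed:
        latent = rng.normal(config.mu_fp, config.sigma, size=n)
    else:
        means = np.where(labels_arr == "TP", config.mu_tp, config.mu_fp).astype(float)
        un = labels_arr == "UN"
        if un.any():
            hi = rng.random(int(un.sum())) < 0.5
            means[un] = np.where(hi, config.mu_tp, config.mu_fp)
        latent = rng.normal(means, config.sigma)

    cols = {}
    for j in range(config.n_columns):
        noise = (
            rng.normal(0.0, config.replicate_sd, size=n)
            if config.replicate_sd > 0
            else 0.0
        )
        cols[f"ratio_{j + 1}"] = np.exp2(latent + noise)
    table = RatioTable(pd.DataFrame(cols, index=pd.Index(accs, name="accession")))
    ref = ReferenceSet(
        tp=frozenset(a for a, l in zip(accs, labels) if l == "TP"),
        fp=frozenset(a for a, l in zip(accs, labels) if l == "FP"),
        provenance=f"synthetic seed={config.seed}",
    )
    truth = pd.DataFrame(
        {"accession": accs, "group": labels, "latent_log2": latent}
    )
    return table, ref, truth


def subsample_reference(
    ref: ReferenceSet, fraction_tp: float, fraction_fp: float, seed: int
) -> ReferenceSet:
    """Uniform random subsets of the TP/FP references (deterministic per seed).

    Mirrors reduced-coverage annotation databases; the cutoff should be
    robust to this.
    """
    if not (0 < fraction_tp <= 1 and 0 < fraction_fp <= 1):
        raise ValueError("fractions must be in (0, 1]")
    rng = np.random.default_rng(seed)

    def pick(accs: frozenset[str], fraction: float) -> frozenset[str]:
        pool = sorted(accs)
        n_keep = round(fraction * len(pool))
        if n_keep == 0:
            raise ValueError(f"fraction {fraction} yields an empty reference set")
        return frozenset(rng.choice(pool, size=n_keep, replace=False))

    return ReferenceSet(
        tp=pick(ref.tp, fraction_tp),
        fp=pick(ref.fp, fraction_fp),
        provenance=f"{ref.provenance} (subsampled tp={fraction_tp}, fp={fraction_fp})",
    )
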