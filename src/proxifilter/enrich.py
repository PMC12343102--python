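"""Over-representation analysis of a retained proteome against flat term sets.

Hypergeometric upper-tail test per term with Benjamini-Hochberg FDR across
the collection. Terms are flat accession sets (no ontology-graph
propagation); annotation input is a 2-column TSV (term<TAB>accession) or
GMT.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .accession import DEFAULT_POLICY, AccessionPolicy, normalize_accession

__all__ = ["AnnotationCollection", "OraResult", "ora", "read_annotations"]


@dataclass
class AnnotationCollection:
    """Map of term id -> (display name, accession set)."""

    terms: dict[str, tuple[str, frozenset[str]]]
    namespace: str = ""

    def __post_init__(self) -> None:
        for term_id, (_, accs) in self.terms.items():
            if not accs:
                raise ValueError(f"term {term_id!r} has an empty accession set")

    def __len__(self) -> int:
        return len(self.terms)


@dataclass
class OraResult:
    """Per-term enrichment table sorted by p-value.

    Columns: term, name, k (hits in study), n (study size), K (hits in
    background), N (background size), fold_enrichment, p, fdr.
    """

    table: pd.DataFrame
    study_size: int = field(default=0)
    background_size: int = field(default=0)


def read_annotations(
    path: str | Path,
    names: Mapping[str, str] | None = None,
    namespace: str = "",
    policy: AccessionPolicy = DEFAULT_POLICY,
) -> AnnotationCollection:
    """Load term->accession pairs from 2-column TSV, or GMT if suffix is .gmt."""
    path = Path(path)
    terms: dict[str, set[str]] = {}
    term_names: dict[str, str] = dict(names or {})
    if path.suffix.lower() == ".gmt":
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            term, name, accs = fields[0], fields[1], fields[2:]
            term_names.setdefault(term, name or term)
            terms.setdefault(term, set()).update(
                normalize_accession(a, policy) for a in accs if a.strip()
            )
    else:
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            term, acc = line.split("\t")[:2]
            terms.setdefault(term, set()).add(normalize_accession(acc, policy))
    return AnnotationCollection(
        {t: (term_names.get(t, t), frozenset(a)) for t, a in terms.items() if a},
        namespace=namespace,
    )


def ora(
    study: Iterable[str],
    background: Iterable[str],
    annotations: AnnotationCollection,
) -> OraResult:
    """Hypergeometric over-representation test of ``study`` within ``background``.

    For a term annotating K of the N background proteins, the p-value is
    the upper-tail probability of observing >= k of them among the n study
    proteins under random draws without replacement. Fold enrichment is
    (k/n) / (K/N). FDR is Benjamini-Hochberg across all terms that overlap
    the background; terms with no background overlap are skipped.
    """
    study_set = frozenset(study)
    bg_set = frozenset(background)
    if not study_set:
        raise ValueError("study set is empty")
    if not study_set <= bg_set:
        missing = sorted(study_set - bg_set)[:5]
        raise ValueError(f"study set not contained in background (e.g. {missing})")
    n, N = len(study_set), len(bg_set)

    rows = []
    for term_id, (name, accs) in annotations.terms.items():
        K = len(accs & bg_set)
        if K == 0:
            continue
        k = len(accs & study_set)
        p = float(hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N)
        rows.append((term_id, name, k, n, K, N, fold, p))
    table = pd.DataFrame(
        rows,
        columns=["term", "name", "k", "n", "K", "N", "fold_enrichment", "p"],
    )
    if len(table):
        table["fdr"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
        table = table.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
    else:
        table["fdr"] = pd.Series(dtype=float)
    return OraResult(table=table, study_size=n, background_size=N)
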