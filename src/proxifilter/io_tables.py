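"""Reading and writing of ratio tables, reference lists, and result tables.

The on-disk contract is deliberately plain: delimited text with a header
row for quantification tables, one accession per line (``#`` comments) for
reference lists, TSV for every result table, and a YAML manifest naming the
files a run produced.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .accession import DEFAULT_POLICY, AccessionPolicy, normalize_accession
from .errors import FormatError, ReferenceError_

if TYPE_CHECKING:  # pragma: no cover
    from .core import CutoffResult, EnrichmentCurve

logger = logging.getLogger(__name__)

__all__ = [
    "RatioTable",
    "ReferenceSet",
    "read_ratio_table",
    "write_ratio_table",
    "read_reference",
    "write_results",
]

#: Significant digits used for every numeric text output.
OUTPUT_PRECISION = 6


@dataclass
class RatioTable:
    """Accession-keyed table of positive labeled-to-control ratios.

    ``data`` is a float DataFrame indexed by unique normalized accessions;
    NaN marks a missing cell (absent or non-positive in the source file).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape[1] < 1:
            raise FormatError("ratio table needs at least one ratio column")
        if self.data.index.has_duplicates:
            raise FormatError("ratio table accessions must be unique")
        with np.errstate(invalid="ignore"):
            bad = (self.data.to_numpy() <= 0) | np.isinf(self.data.to_numpy())
        if bad.any():
            raise FormatError("ratio values must be finite and > 0 (or NaN)")

    @property
    def accessions(self) -> list[str]:
        return list(self.data.index)

    @property
    def ratio_columns(self) -> list[str]:
        return list(self.data.columns)

    def column_values(self, column: str) -> pd.Series:
        """Non-missing values of one column, in table row order."""
        return self.data[column].dropna()

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class ReferenceSet:
    """Disjoint true-positive / false-positive accession sets.

    ``tp`` holds curated residents of the target compartment, ``fp`` holds
    known contaminants; the two anchor TPR/FPR along a ranked protein list.
    """

    tp: frozenset[str]
    fp: frozenset[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.tp = frozenset(self.tp)
        self.fp = frozenset(self.fp)
        if self.tp & self.fp:
            raise ReferenceError_("tp and fp reference sets must be disjoint")
        if not self.tp or not self.fp:
            raise ReferenceError_("tp and fp reference sets must be non-empty")


def _sniff_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_ratio_table(
    path: str | Path,
    delimiter: str | None = None,
    accession_column: str | int = 0,
    policy: AccessionPolicy = DEFAULT_POLICY,
) -> RatioTable:
    """Load a delimited quantification table.

    Parameters
    ----------
    path
        CSV/TSV file with a header row.
    delimiter
        Explicit field separator; by default inferred from the extension
        (``.csv`` -> comma, anything else -> tab).
    accession_column
        Name or positional index of the identifier column.
    policy
        Accession normalization policy.

    Notes
    -----
    Cells that do not parse as numbers, or parse to a non-positive or
    non-finite value, are flagged missing (NaN) and counted in the log.
    Columns with no parseable value at all (e.g. free-text annotation
    columns) are dropped. Duplicate accessions keep the first occurrence.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"ratio table not found: {path}")
    raw = pd.read_csv(path, sep=_sniff_delimiter(path, delimiter), dtype=str)
    if raw.shape[1] < 2:
        raise FormatError(f"{path}: need an accession column plus >=1 ratio column")

    if isinstance(accession_column, int):
        acc_name = raw.columns[accession_column]
    else:
        if accession_column not in raw.columns:
            raise FormatError(f"{path}: accession column {accession_column!r} not found")
        acc_name = accession_column

    accessions = [normalize_accession(a, policy) for a in raw[acc_name].astype(str)]
    values = raw.drop(columns=[acc_name])

    numeric = values.apply(pd.to_numeric, errors="coerce")
    keep = [c for c in numeric.columns if numeric[c].notna().any()]
    dropped = [c for c in numeric.columns if c not in keep]
    if dropped:
        logger.info("%s: dropping non-numeric columns %s", path.name, dropped)
    if not keep:
        raise FormatError(f"{path}: no numeric ratio columns found")
    numeric = numeric[keep].astype(float)

    n_unparseable = int((numeric.isna() & values[keep].notna()).to_numpy().sum())
    with np.errstate(invalid="ignore"):
        nonpos = (numeric.to_numpy() <= 0) | np.isinf(numeric.to_numpy())
    if nonpos.any():
        logger.warning(
            "%s: %d non-positive/non-finite ratio cells flagged missing",
            path.name,
            int(nonpos.sum()),
        )
        numeric = numeric.mask(nonpos)
    if n_unparseable:
        logger.warning(
            "%s: %d unparseable cells flagged missing", path.name, n_unparseable
        )

    numeric.index = pd.Index(accessions, name="accession")
    dup_mask = numeric.index.duplicated(keep="first")
    if dup_mask.any():
        for acc in numeric.index[dup_mask]:
            logger.warning("%s: duplicate accession %s dropped (kept first)", path.name, acc)
        numeric = numeric[~dup_mask]

    numeric = numeric.dropna(how="all")
    if numeric.empty:
        raise FormatError(f"{path}: empty table after filtering")
    return RatioTable(numeric)


def _fmt(x: float) -> str:
    return f"{x:.{OUTPUT_PRECISION}g}" if np.isfinite(x) else ""


def write_ratio_table(table: RatioTable, path: str | Path, delimiter: str | None = None) -> None:
    """Write ``table`` as delimited text (round-trips with read_ratio_table)."""
    path = Path(path)
    sep = _sniff_delimiter(path, delimiter)
    out = table.data.map(_fmt)
    out.to_csv(path, sep=sep)


def _read_accession_lines(path: Path, policy: AccessionPolicy) -> list[str]:
    if not path.is_file():
        raise FileNotFoundError(f"reference list not found: {path}")
    accs: list[str] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        accs.append(normalize_accession(line, policy))
    return accs


def read_reference(
    tp_path: str | Path,
    fp_path: str | Path,
    policy: AccessionPolicy = DEFAULT_POLICY,
    provenance: str = "",
) -> ReferenceSet:
    """Load TP/FP reference lists; accessions in both lists are dropped from both."""
    tp = set(_read_accession_lines(Path(tp_path), policy))
    fp = set(_read_accession_lines(Path(fp_path), policy))
    conflicts = tp & fp
    for acc in sorted(conflicts):
        logger.warning("accession %s present in both references; removed from both", acc)
    tp -= conflicts
    fp -= conflicts
    if not tp or not fp:
        raise ReferenceError_(
            f"reference empty after loading (tp={len(tp)}, fp={len(fp)})"
        )
    return ReferenceSet(frozenset(tp), frozenset(fp), provenance=provenance)


_SLUG_RE = re.compile(r"[^A-Za-z0-9._-]+")


def column_slug(name: str) -> str:
    """Filesystem-safe token for a column name (``129C:127N`` -> ``129C-127N``)."""
    return _SLUG_RE.sub("-", name).strip("-") or "column"


def write_results(
    outdir: str | Path,
    result: "CutoffResult",
    curves: Iterable["EnrichmentCurve"],
    top_tables: Mapping[str, pd.DataFrame],
) -> dict[str, object]:
    """Write the post-cutoff proteome, per-column curve tables, and top-N tables.

    Returns a manifest (also written as ``manifest.yaml``) mapping logical
    names to the file paths produced. Deterministic: identical inputs give
    byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    proteome_path = outdir / "final_proteome.txt"
    proteome_path.write_text(
        "".join(f"{acc}\n" for acc in sorted(result.final_proteome))
    )

    columns = list(result.per_column_retained)
    all_accs = sorted(set().union(*result.per_column_retained.values(), result.final_proteome))
    flags = pd.DataFrame(
        {
            c: [acc in result.per_column_retained[c] for acc in all_accs]
            for c in columns
        },
        index=pd.Index(all_accs, name="accession"),
    )
    flags["final"] = [acc in result.final_proteome for acc in all_accs]
    flags_path = outdir / "proteome_flags.tsv"
    flags.replace({True: "pass", False: "fail"}).to_csv(flags_path, sep="\t")

    manifest: dict[str, object] = {
        "final_proteome": str(proteome_path),
        "proteome_flags": str(flags_path),
        "curves": {},
        "top_tables": {},
    }
    for curve in curves:
        slug = column_slug(curve.column_name)
        cpath = outdir / f"curve_{slug}.tsv"
        df = curve.to_frame()
        for col in ("ratio", "tpr", "fpr", "diff"):
            df[col] = df[col].map(_fmt)
        df.to_csv(cpath, sep="\t", index=False)
        manifest["curves"][curve.column_name] = str(cpath)
    for name, table in top_tables.items():
        slug = column_slug(name)
        tpath = outdir / f"top_{slug}.tsv"
        out = table.copy()
        if "ratio" in out.columns:
            out["ratio"] = out["ratio"].map(_fmt)
        out.to_csv(tpath, sep="\t", index=False)
        manifest["top_tables"][name] = str(tpath)

    manifest_path = outdir / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    manifest["manifest"] = str(manifest_path)
    return manifest
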