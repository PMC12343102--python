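"""Protein identifier normalization.

Quantification tables and reference lists frequently disagree on identifier
style: isoform suffixes (``P12345-2``), FASTA-header tokens
(``sp|P12345|NAME_MOUSE``), or case. Normalization makes them key-match.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["AccessionPolicy", "DEFAULT_POLICY", "normalize_accession"]


@dataclass(frozen=True)
class AccessionPolicy:
    """Switches controlling identifier canonicalization.

    Attributes
    ----------
    strip_isoform
        Remove a trailing ``-N`` isoform suffix (``P12345-2`` -> ``P12345``).
    parse_fasta_header
        Extract the accession from ``db|ACC|NAME`` style tokens.
    case_fold
        Uppercase the identifier.
    """

    strip_isoform: bool = True
    parse_fasta_header: bool = True
    case_fold: bool = True


#: Default policy: reference lists are gene-level, so isoform suffixes would
#: silently zero the TP/FP hit counts if kept.
DEFAULT_POLICY = AccessionPolicy()

_ISOFORM_RE = re.compile(r"^([A-Za-z0-9]+)-\d+$")


def normalize_accession(raw: str, policy: AccessionPolicy = DEFAULT_POLICY) -> str:
    """Return the canonical form of ``raw`` under ``policy``.

    Idempotent: ``normalize_accession(normalize_accession(x)) ==
    normalize_accession(x)`` for any input and policy.

    Raises
    ------
    ValueError
        If ``raw`` is empty or whitespace-only.
    """
    acc = raw.strip()
    if not acc:
        raise ValueError("empty accession string")
    if policy.parse_fasta_header and "|" in acc:
        fields = [f.strip() for f in acc.split("|")]
        if len(fields) >= 2 and fields[1]:
            acc = fields[1]
    if policy.case_fold:
        acc = acc.upper()
    if policy.strip_isoform:
        m = _ISOFORM_RE.match(acc)
        if m:
            acc = m.group(1)
    return acc
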