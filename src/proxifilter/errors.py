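"""Exception hierarchy used across the package.

All errors raised on bad user input derive from :class:`ProxifilterError`
so the CLI can catch them in one place and exit nonzero with a tagged
message.
"""


class ProxifilterError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ProxifilterError):
    """Input file violates the expected tabular format."""


class ReferenceError_(ProxifilterError):
    """Reference lists are unusable (empty after loading, etc.)."""


class AnalysisError(ProxifilterError):
    """A computation precondition failed (e.g. reference does not overlap data)."""


class QCError(ProxifilterError):
    """Replicate-consistency assessment cannot be performed."""
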