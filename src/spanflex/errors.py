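"""Exception hierarchy shared across the package."""


class SpanflexError(Exception):
    """Base class for all package-specific errors."""


class ParseError(SpanflexError):
    """A file could not be parsed (PDB, SAXS .dat, config)."""


class ValidationError(SpanflexError):
    """Inputs violate a documented contract (negative weight, missing role, ...)."""


class StructuralError(SpanflexError):
    """Structural mismatch, e.g. state count vs weight-table row count."""


class ResolutionError(SpanflexError):
    """A named selection resolved to no atoms (or mismatched atom counts)."""


class RankError(SpanflexError):
    """Geometry too degenerate for the requested operation (collinear, <3 atoms)."""


class FitError(SpanflexError):
    """A model fit failed (non-decaying Guinier region, degenerate weights, ...)."""


class ConvergenceError(FitError):
    """An iterative fit failed to converge or its window collapsed."""


class NormalizationError(SpanflexError):
    """A normalization reference was invalid (non-positive scale, ...)."""


class SizeError(SpanflexError):
    """Problem size exceeds a documented limit (e.g. exhaustive subset pool)."""
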