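"""Exception hierarchy shared by all excompose modules."""


class ExcomposeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ExcomposeError):
    """A file does not conform to its documented layout (bad header, bad token)."""


class ParseError(ExcomposeError):
    """A cell or line could not be converted to its expected type."""


class ValidationError(ExcomposeError):
    """A parsed value violates a domain invariant (e.g. negative frequency)."""


class MissingTermError(ExcomposeError):
    """A composite-energy term is required but absent for a conformer/method."""


class FitError(ExcomposeError):
    """A regression cannot be performed (too few or degenerate points)."""


class GeometryError(ExcomposeError):
    """Degenerate geometry (collinear atoms, rank-deficient subset)."""


class EmptyComparisonError(ExcomposeError):
    """No overlapping pairs remain after alignment/exclusion."""


class UsageError(ExcomposeError):
    """An operation was called with inconsistent arguments."""
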