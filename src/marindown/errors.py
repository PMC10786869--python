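"""Exception types shared across the package.

``ValidationError`` signals malformed or inconsistent inputs (bad shapes,
unsorted coordinates, empty periods); ``DomainError`` signals inputs that are
well-formed but outside the mathematical domain of an operation (disjoint
grids, no valid source points, extrapolation requests).
"""


class MarindownError(Exception):
    """Base class for all package errors."""


class ValidationError(MarindownError, ValueError):
    """Input fails a structural or consistency check."""


class DomainError(MarindownError, ValueError):
    """Input is structurally valid but outside the operation's domain."""
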