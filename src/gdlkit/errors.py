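"""Exception hierarchy for gdlkit.

All package-specific failures derive from :class:`GdlError` so callers can
catch one base class at tool boundaries.
"""


class GdlError(Exception):
    """Base class for all gdlkit errors."""


class StreamParseError(GdlError):
    """A frame-stream file is malformed.

    Carries the 1-based line number of the offending record when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class TopologyError(GdlError):
    """Skeleton data does not match the declared joint topology."""


class FormatError(GdlError):
    """A BVH (or other foreign) file violates its format."""


class ExpressionError(GdlError):
    """A feature/rule expression failed to parse or type-check."""


class ValidationError(GdlError):
    """A definition references unknown joints/features or has the wrong type."""


class DegenerateVectorError(GdlError):
    """An angle was requested of a zero-length vector.

    ``operand`` names which argument was degenerate; ``timestamp`` and
    ``feature`` are filled in when the error surfaces during per-frame
    feature evaluation.
    """

    def __init__(self, operand: str, timestamp: float | None = None,
                 feature: str | None = None):
        self.operand = operand
        self.timestamp = timestamp
        self.feature = feature
        msg = f"zero-length {operand} vector in angle()"
        if feature is not None:
            msg += f" while evaluating feature {feature!r}"
        if timestamp is not None:
            msg += f" at t={timestamp}"
        super().__init__(msg)


class OrderingError(GdlError):
    """Timestamps regressed (streams must be time-ordered)."""


class InsufficientDataError(GdlError):
    """Too few rows/exemplars for the requested training operation."""
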