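"""Exception types shared across the package."""


class PentrackError(Exception):
    """Base class for all package-specific errors."""


class InvalidBoxError(PentrackError, ValueError):
    """A bounding box with non-positive width or height."""


class InvalidMeasurementError(PentrackError, ValueError):
    """A measurement vector with non-positive aspect ratio or height."""


class NumericalError(PentrackError, ArithmeticError):
    """A linear-algebra step failed (e.g. non-PD innovation covariance)."""


class SequencingError(PentrackError, ValueError):
    """Frames fed to the tracker out of order."""


class ConfigError(PentrackError, ValueError):
    """An infeasible or inconsistent configuration."""


class ParseError(PentrackError, ValueError):
    """A malformed input file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class UndefinedMetricError(PentrackError, ZeroDivisionError):
    """A metric whose denominator is empty (no positives, no matches...)."""
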