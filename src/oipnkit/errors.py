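"""Exception hierarchy.

Everything derives from :class:`ValueError` so callers who only care that an
input was bad can catch one type, while the finer classes mirror the distinct
failure modes of the pipeline (bad configuration, malformed input tables,
degenerate contingency tables, infeasible marginals, bad geometry, and
threshold-estimation failures).
"""


class OipnkitError(ValueError):
    """Base class for all package-specific errors."""


class ConfigurationError(OipnkitError):
    """A generator or analysis configuration value is out of range."""


class ParseError(OipnkitError):
    """A report table row could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DegenerateTableError(OipnkitError):
    """A 2x2 table has a zero cell or zero marginal where the statistic is undefined."""


class InfeasibleMarginalsError(OipnkitError):
    """Printed marginal rates admit no integer 2x2 table."""


class GeometryError(OipnkitError):
    """A fiber boundary is degenerate (zero perimeter, self-intersecting, ...)."""


class EstimationError(OipnkitError):
    """An up-down series cannot be reduced to a threshold estimate."""
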