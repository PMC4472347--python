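"""Exception hierarchy shared across the package."""


class MethriskError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MethriskError, ValueError):
    """A configuration object or file violates its invariants."""


class ValidationError(MethriskError, ValueError):
    """Input data violate a documented precondition."""


class ParseError(MethriskError, ValueError):
    """A delimited input file could not be parsed.

    Carries the 1-based line number of the offending record when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UndefinedMeasurementError(MethriskError, ValueError):
    """A quantity is undefined for the given input (e.g. 0 total copies)."""


class ConvergenceError(MethriskError, RuntimeError):
    """A model fit failed and no result can be reported."""


class CutpointError(MethriskError, ValueError):
    """No admissible cutpoint candidate exists under the constraints."""


class UnderpoweredError(MethriskError, ValueError):
    """Too few records or events for the requested analysis."""
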