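"""Exception hierarchy shared across the package."""


class LncdissectError(Exception):
    """Base class for all package errors."""


class ValidationError(LncdissectError, ValueError):
    """An input violated a documented precondition or invariant."""


class GtfParseError(ValidationError):
    """A GTF line could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class GenerationError(LncdissectError):
    """The synthetic-data generator could not satisfy its placement constraints."""


class ConstantVectorError(ValidationError):
    """Correlation requested on a zero-variance vector; the caller must skip it."""


class ClassificationError(LncdissectError):
    """Internal contract violation: a called lncRNA could not be classed."""
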