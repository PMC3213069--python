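"""Exception hierarchy shared across the package."""


class NmrMatchError(Exception):
    """Base class for all nmrmatch errors."""


class ParseError(NmrMatchError):
    """A text input could not be parsed.

    Carries the 1-based line number when it is known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(NmrMatchError):
    """A domain invariant was violated (bad peak, record, or library)."""


class ConfigurationError(NmrMatchError):
    """An operation was configured with inconsistent or infeasible parameters."""


class EmptyInputError(NmrMatchError):
    """A search was attempted on an empty query peak list."""
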