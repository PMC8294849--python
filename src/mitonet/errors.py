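"""Exception types shared across the pipeline.

Undefined quantities (a velocity with all time excluded, a distance with no
mitochondrial signal, a Gaussian fit that does not converge) are raised as
distinct signals rather than returned as sentinel numbers, so callers can
never mistake them for zero.
"""


class MitonetError(Exception):
    """Base class for all package errors."""


class ParameterError(MitonetError, ValueError):
    """A requested construction or analysis parameter is impossible."""


class InputError(MitonetError, ValueError):
    """Input data violate a precondition (shape, monotonicity, emptiness)."""


class ParseError(MitonetError, ValueError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UndefinedResultError(MitonetError, ArithmeticError):
    """The requested quantity is undefined for this input (not zero)."""


class FitError(MitonetError, RuntimeError):
    """A model fit failed to converge; no default value is substituted."""
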