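"""Exception hierarchy shared across the package.

Validation failures (bad inputs, malformed files, precondition violations)
and numerical failures (non-convergence, rank deficiency) are distinguished
so the command-line layer can map them to distinct exit codes.
"""


class SeedLipidError(Exception):
    """Base class for all package errors."""


class ValidationError(SeedLipidError, ValueError):
    """Input violates a documented precondition or invariant."""


class RangeError(ValidationError):
    """A requested interval does not overlap the data."""


class DegenerateInputError(ValidationError):
    """Input is formally valid but degenerate (all-zero table, constant row)."""


class InconsistentIntegralsError(ValidationError):
    """Integral ratios imply an acyl composition outside [0, 100] beyond tolerance."""


class ParseError(ValidationError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class NumericalError(SeedLipidError, ArithmeticError):
    """An iterative or linear-algebra step failed numerically."""
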