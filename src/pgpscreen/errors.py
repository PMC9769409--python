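"""Exception hierarchy shared across the package.

Three broad failure classes map onto distinct CLI exit codes: I/O problems
(missing files), format/validation problems (malformed or out-of-range data),
and configuration problems (invalid rule sets or simulation settings).
"""


class PgpScreenError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PgpScreenError):
    """A table does not have the required structure (columns, emptiness)."""


class TableParseError(FormatError):
    """A cell could not be parsed; names the offending row and column."""

    def __init__(self, message: str, row: object = None, column: str | None = None):
        super().__init__(message)
        self.row = row
        self.column = column


class ValidationError(PgpScreenError):
    """A parsed value violates a domain invariant (e.g. percent outside [0, 100])."""


class DomainError(ValidationError):
    """An operation was called with arguments outside its mathematical domain."""


class DegenerateDesignError(DomainError):
    """A calibration/regression design carries no usable signal."""


class DegenerateColumnError(DomainError):
    """A data matrix column is constant and cannot be standardized."""

    def __init__(self, message: str, column: str | None = None):
        super().__init__(message)
        self.column = column


class ConfigurationError(PgpScreenError):
    """A rule set or simulation configuration is self-inconsistent."""
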