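"""Exception hierarchy shared across the package."""


class ArstratError(Exception):
    """Base class for all package errors."""


class SchemaError(ArstratError):
    """Input table does not match the expected column schema."""


class ValidationError(ArstratError):
    """A cell value violates a domain invariant (names row and column)."""

    def __init__(self, message: str, row=None, column=None):
        super().__init__(message)
        self.row = row
        self.column = column


class ConfigurationError(ArstratError):
    """Invalid generator / analysis configuration."""


class MissingDataError(ArstratError):
    """An operation requires non-missing values that are absent."""
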