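"""Exception hierarchy shared across the package."""


class TracerLakeError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(TracerLakeError):
    """A CSV file is missing mandatory columns or has an unusable layout."""


class ValidationError(TracerLakeError):
    """One or more records violate domain invariants.

    ``rows`` holds 1-based data-row numbers of the offending records when the
    error originates from file ingestion.
    """

    def __init__(self, message: str, rows: list[int] | None = None):
        super().__init__(message)
        self.rows = rows or []


class InsufficientDataError(TracerLakeError):
    """Too few observations to perform the requested fit or test."""


class SingularDesignError(TracerLakeError):
    """The regression design matrix is rank deficient (e.g. all lengths equal)."""


class UndefinedResultError(TracerLakeError):
    """The requested quantity is mathematically undefined for the fitted model."""
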