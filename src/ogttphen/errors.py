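"""Exception hierarchy shared by all pipeline stages."""


class CohortError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CohortError):
    """Input table does not match the declared cohort schema."""


class RowValidationError(CohortError):
    """A single row violates a record invariant.

    Carries the offending patient id and field name so that failures can
    be traced back to the source row.
    """

    def __init__(self, patient_id: str, field: str, message: str):
        self.patient_id = patient_id
        self.field = field
        super().__init__(f"record {patient_id!r}, field {field!r}: {message}")


class UnitConfigError(CohortError):
    """Unknown or inconsistent measurement-unit configuration."""


class MissingDataError(CohortError):
    """An operation requires data (e.g. a complete OGTT) that is absent."""


class DomainError(CohortError, ValueError):
    """Input is outside the mathematical domain of an operation."""


class CollinearityError(DomainError):
    """Regression design matrix is rank deficient."""

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(message or f"collinear design columns: {self.columns}")


class ParameterError(CohortError, ValueError):
    """Invalid simulation or configuration parameters."""
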