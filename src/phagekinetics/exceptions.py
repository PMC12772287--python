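"""Exception hierarchy.

Every failure mode the pipeline distinguishes gets its own class so callers
(and the CLI) can report which stage and which record failed.
"""


class PhageKineticsError(Exception):
    """Base class for all package errors."""


class SchemaError(PhageKineticsError):
    """An input table is missing required columns or a report payload has
    unexpected field names."""


class RowValidationError(PhageKineticsError):
    """A single input row failed validation; carries the 0-based row index."""

    def __init__(self, row_index: int, message: str):
        self.row_index = row_index
        super().__init__(f"row {row_index}: {message}")


class ConfigurationError(PhageKineticsError):
    """Invalid experiment or simulation configuration."""


class InsufficientDataError(PhageKineticsError):
    """Too few data points for the requested computation."""


class NoQuantitativeDataError(InsufficientDataError):
    """A timepoint produced no quantitative (non-zero, non-TNTC) measurements."""


class DomainError(PhageKineticsError, ValueError):
    """Mathematical domain violation (log of non-positive value, division by
    an exactly-zero value, k at t = 0)."""


class DegenerateVarianceError(PhageKineticsError):
    """Both groups of a two-sample comparison have zero spread; the t statistic
    is undefined and no p-value is reported."""


class AssayError(PhageKineticsError):
    """The measurements contradict the assay design (e.g. initial free phage
    at or above initial total phage, so no infected cells can be inferred)."""
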