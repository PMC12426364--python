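"""Exception hierarchy.

``ValidationError`` subclasses map to CLI exit code 2, ``NumericalError``
to exit code 3.
"""


class DutycastError(Exception):
    """Base class for all package errors."""


class ValidationError(DutycastError):
    """Invalid inputs, schemas, or configuration."""


class GapError(ValidationError):
    """Monthly panel has missing (month, category) cells."""


class SchemaError(ValidationError):
    """Column mapping or category labels do not match the table."""


class ParseError(ValidationError):
    """A cell could not be parsed; message carries the row location."""


class DomainError(ValidationError):
    """Value outside the mathematical domain (e.g. log of a non-positive)."""


class CoverageError(ValidationError):
    """A price index or interval set does not cover the requested months."""


class AlignmentError(ValidationError):
    """Two monthly objects do not align on the same months."""


class NumericalError(DutycastError):
    """Numerical failure (rank deficiency, non-PSD covariance, ...)."""
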