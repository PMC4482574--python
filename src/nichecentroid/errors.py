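"""Exception hierarchy shared across the pipeline.

Every error raised by this package derives from :class:`NicheCentroidError`
so callers can catch the whole family with one clause while tests pin the
specific subclass a contract violation must produce.
"""


class NicheCentroidError(Exception):
    """Base class for all package errors."""


class ContractError(NicheCentroidError):
    """A precondition on arguments was violated (dimension, geometry, range)."""


class AlignmentError(ContractError):
    """Raster layers do not share grid geometry or CRS."""


class SchemaError(NicheCentroidError):
    """A tabular input is missing required columns."""


class DataValidationError(NicheCentroidError):
    """A tabular input has invalid values (e.g. negative counts)."""


class InsufficientDataError(NicheCentroidError):
    """Too few records to perform the requested estimation."""


class EmptyResultError(NicheCentroidError):
    """An operation produced no usable records (e.g. all points off-grid)."""


class FitDomainError(NicheCentroidError):
    """Data violate the domain of a curve family (e.g. y<=0 for log forms).

    Carries the indices of the offending records so nothing is silently
    excluded.
    """

    def __init__(self, message, offending=None):
        super().__init__(message)
        self.offending = list(offending) if offending is not None else []


class ConfigError(NicheCentroidError):
    """A synthetic-landscape configuration is invalid."""
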