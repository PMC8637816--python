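"""Exception hierarchy shared across the package."""

__all__ = [
    "LipLeadError",
    "SchemaError",
    "ValidationError",
    "ParameterError",
    "FitError",
    "DegenerateDistributionError",
    "UndefinedCorrelationError",
    "UndefinedRpdError",
]


class LipLeadError(Exception):
    """Base class for all package errors."""


class SchemaError(LipLeadError, ValueError):
    """An input table does not match the documented column schema."""


class ValidationError(LipLeadError, ValueError):
    """A value violates a documented invariant (e.g. negative concentration)."""


class ParameterError(LipLeadError, ValueError):
    """A model parameter is outside its admissible range."""


class FitError(LipLeadError, ValueError):
    """Too little usable data to fit a concentration distribution."""


class DegenerateDistributionError(FitError):
    """The positive concentrations have zero spread; no lognormal fits."""


class UndefinedCorrelationError(LipLeadError, ValueError):
    """A correlation was requested on a constant variable."""


class UndefinedRpdError(LipLeadError, ValueError):
    """A replicate pair has mean zero, so relative deviation is undefined."""
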