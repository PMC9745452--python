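"""Exception hierarchy for lesionkinetics."""


class LesionKineticsError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(LesionKineticsError, ValueError):
    """A record or domain value violates an invariant.

    Parameters
    ----------
    message : str
        Human-readable description of the violation.
    field : str, optional
        Name of the offending field, when attributable to one.
    """

    def __init__(self, message: str, field: str | None = None):
        super().__init__(message)
        self.field = field


class SchemaError(LesionKineticsError, ValueError):
    """A tabular input does not conform to the expected CSV schema."""

    def __init__(self, message: str, column: str | None = None):
        super().__init__(message)
        self.column = column


class EmptyDatasetError(LesionKineticsError, ValueError):
    """No usable records remain (or were supplied)."""


class FitInputError(LesionKineticsError, ValueError):
    """Input data unsuitable for the requested fit or estimator."""


class DegenerateFitError(LesionKineticsError, RuntimeError):
    """A downstream operation refused to run on a degenerate/unconverged fit."""


class ModelError(LesionKineticsError, ValueError):
    """Operation undefined for the fitted model class."""


class UnreachableThresholdError(LesionKineticsError, ValueError):
    """Requested response level lies at or above the fitted plateau."""

    def __init__(self, message: str, ymax: float | None = None):
        super().__init__(message)
        self.ymax = ymax


class ZeroVarianceError(LesionKineticsError, ValueError):
    """A statistic is undefined because the pooled data have zero variance."""


class NoRiseError(LesionKineticsError, ValueError):
    """An empirical trace shows no positive rate of change to analyse."""


class CalibrationError(LesionKineticsError, ValueError):
    """Generator-truth calibration inputs are inconsistent."""


class ConfigError(LesionKineticsError, ValueError):
    """An experiment configuration is invalid or incomplete."""
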