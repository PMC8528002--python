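"""Exception and warning hierarchy for the assay toolkit."""


class QPAError(Exception):
    """Base class for all assay-specific errors."""


class InvalidInputError(QPAError, ValueError):
    """An argument violates a stated precondition (sign, range, units)."""


class InsufficientDataError(QPAError):
    """Too few readings / time points to perform the requested estimate."""


class InsufficientCellsError(QPAError):
    """Fewer gated events than the minimum cell count for a robust median."""


class InvalidIntervalError(QPAError, ValueError):
    """A time interval with t_end <= t_start or outside the series range."""


class ParseError(QPAError):
    """Malformed instrument or layout file; message names the offending line."""


class ChannelMappingError(ParseError):
    """A required cytometer channel cannot be resolved to a canonical name."""


class DegenerateCalibrationError(QPAError):
    """Bead calibration attempted with fewer than two distinct diameters."""


class CalibrationRangeError(QPAError):
    """A calibrated quantity (e.g. cell size) fell outside its valid range."""


class MissingMetadataError(QPAError):
    """A required acquisition metadata field (e.g. volume) is absent."""


class FitFailureError(QPAError):
    """Nonlinear fit failed to converge from every starting point."""


class ReconciliationError(QPAError):
    """Trait results that cannot be matched one-to-one onto layout wells."""


class InvalidDesignError(QPAError):
    """A permutation-test design with too few groups or aliased factors."""


class DecompositionError(QPAError):
    """Degenerate (zero-rank) input to an ordination."""


class QualityWarning(UserWarning):
    """Non-fatal data-quality flag (e.g. negative stain delta retained)."""
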