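"""Exception hierarchy for the ebcentroid package."""


class EBCentroidError(Exception):
    """Base class for all package-specific errors."""


class CalibrationError(EBCentroidError):
    """Camera calibration is invalid (non-positive gain or pixel size, …)."""


class EmptyStackError(EBCentroidError):
    """An operation that needs frames was given an empty stack."""


class DegenerateInputError(EBCentroidError):
    """Input too small or too uniform for the requested operation."""


class EstimationError(EBCentroidError):
    """A robust estimate could not be formed (e.g. all frames ion-flagged)."""


class OutOfBoundsError(EBCentroidError):
    """A candidate or region lies outside the frame."""


class ConfigError(EBCentroidError):
    """Pipeline configuration failed validation."""
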