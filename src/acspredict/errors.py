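"""Exception hierarchy shared across the pipeline stages."""


class AcsPredictError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(AcsPredictError):
    """Invalid configuration value; carries the offending field name."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field {field!r}: {message}")


class SimulationInfeasibleError(AcsPredictError):
    """The requested synthetic cohort cannot be generated."""


class CalibrationError(AcsPredictError):
    """Migration-time calibration failed; carries the anchor count."""

    def __init__(self, n_anchors: int, message: str):
        self.n_anchors = n_anchors
        super().__init__(message)


class NormalizationError(AcsPredictError):
    """Housekeeping-based amplitude normalization failed."""


class ValidationError(AcsPredictError):
    """Input table failed structural validation."""


class EvaluationError(AcsPredictError):
    """A performance statistic is undefined on the given input."""
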