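"""Exception hierarchy for pleurisk."""


class PleuriskError(Exception):
    """Base class for all package-specific errors."""


class CohortValidationError(PleuriskError):
    """Raised when tabular input violates the cohort data model."""


class SeparationError(PleuriskError):
    """Complete or quasi-complete separation in a logistic fit.

    Diverging maximum-likelihood estimates (|slope| beyond ``SLOPE_LIMIT``
    on the log10 scale, or perfect prediction) make the fit meaningless;
    the gated first step of the two-step model exists precisely to keep
    the regression away from this regime.
    """

    def __init__(self, message: str, predictors: tuple[str, ...] = ()):
        super().__init__(message)
        self.predictors = predictors


class DegenerateDataError(PleuriskError):
    """Input carries no usable variation (constant predictor, zero IQR,
    zero rank variance, all-0.5 forecasts, ...)."""


class PipelineError(PleuriskError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
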