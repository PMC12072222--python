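"""Exception hierarchy for model construction, calibration and estimation."""


class ModelError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(ModelError, ValueError):
    """A parameter value violates its physical or structural constraints."""


class DegenerateModelError(ModelError):
    """The model structure admits no meaningful solution (e.g. no elimination)."""


class CalibrationError(ModelError):
    """A calibration target is unattainable or the scaler is unset."""


class InfeasibleObservationError(ModelError):
    """An observed interaction ratio exceeds what the model can produce.

    Carries the attainable ceiling so callers can report it.
    """

    def __init__(self, message: str, ceiling: float | None = None):
        super().__init__(message)
        self.ceiling = ceiling


class AmbiguousVictimError(ModelError):
    """A victim compound has both endogenous synthesis and exogenous dosing."""


class SteadyStateError(ModelError):
    """A multiple-dose simulation did not reach a certified steady state."""
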