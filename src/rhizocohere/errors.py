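"""Exception and warning types shared across the pipeline."""


class RhizocohereError(Exception):
    """Base class for all package-specific errors."""


class NoSignalError(RhizocohereError):
    """Raised when every sample of a force trace lies below the noise threshold."""


class InvalidTraceError(RhizocohereError):
    """Raised for malformed force-displacement traces (e.g. decreasing displacement)."""


class InsufficientDataError(RhizocohereError):
    """Raised when a fit is requested with too few points or no usable design."""


class FitFailureError(RhizocohereError):
    """Raised when a nonlinear least-squares fit fails to converge."""


class IterationFailureError(RhizocohereError):
    """Raised when a fixed-point iteration does not converge within its budget."""


class CalibrationError(RhizocohereError):
    """Raised when mechanistic-model calibration is infeasible or under-determined."""


class NegativeCohesionWarning(UserWarning):
    """Emitted when a detachment efficiency exceeds the zero-cohesion ceiling (beta > 0.79)."""


class BareSoilUnerodedWarning(UserWarning):
    """Emitted when the applied shear does not exceed even the bare-soil cohesion."""
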