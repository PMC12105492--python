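"""Exception and warning types shared across the package."""


class PhytowaveError(Exception):
    """Base class for all package-specific errors."""


class DomainError(PhytowaveError, ValueError):
    """An argument lies outside the physically meaningful domain."""


class DegenerateInputError(PhytowaveError, ValueError):
    """Input is structurally valid but carries no usable information
    (e.g. fewer than two distinct concentrations, an empty window)."""


class NonInvertibleError(PhytowaveError, ValueError):
    """A calibration curve with zero sensitivity cannot map response
    back to concentration."""


class NonIdentifiableError(PhytowaveError, ValueError):
    """The data do not constrain the parameter being fitted
    (e.g. all-flat traces for a flow fit)."""


class NoWaveDetected(PhytowaveError):
    """No threshold crossing was found after the stimulus."""


class InfiniteVelocityError(PhytowaveError, ValueError):
    """Two take-off times coincide; a propagation velocity is undefined."""


class StabilityError(PhytowaveError, RuntimeError):
    """The explicit integrator violated a stability bound; the message
    names the offending bound."""


class FitConvergenceError(PhytowaveError, RuntimeError):
    """A nonlinear fit failed to converge; carries residual diagnostics."""


class ExtrapolationWarning(UserWarning):
    """A calibration curve was evaluated outside its fitted range."""


class SignWarning(UserWarning):
    """A velocity pair was supplied in unexpected order."""


class ZeroDistanceWarning(UserWarning):
    """A sensor coincides with the stimulus position."""


class BoundaryWarning(UserWarning):
    """An optimizer terminated at a bound of its search interval."""
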