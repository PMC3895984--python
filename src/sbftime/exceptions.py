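"""Exception types raised across the package."""


class SBFError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SBFError, ValueError):
    """Invalid specification, configuration or argument."""


class IntegrationError(SBFError, RuntimeError):
    """Numerical integration produced a non-finite state."""


class FrequencyRangeError(SBFError, ValueError):
    """Requested firing rate lies outside the achievable f-I band."""

    def __init__(self, target: float, f_lo: float, f_hi: float):
        self.target = target
        self.f_lo = f_lo
        self.f_hi = f_hi
        super().__init__(
            f"target rate {target:g} Hz outside achievable band "
            f"[{f_lo:.3f}, {f_hi:.3f}] Hz"
        )


class CalibrationError(SBFError, RuntimeError):
    """Bank calibration failed (e.g. flat voltage trace, no oscillation)."""


class EncodingError(SBFError, RuntimeError):
    """Reference-memory encoding degenerated (all-zero weights)."""


class EnvelopeError(SBFError, RuntimeError):
    """Trace has too few local maxima to define an upper envelope."""


class FitError(SBFError, RuntimeError):
    """Nonlinear fit failed to converge."""

    def __init__(self, message: str, initial_guess=None, residual=None):
        self.initial_guess = initial_guess
        self.residual = residual
        super().__init__(message)


class TruncationError(SBFError, RuntimeError):
    """Trace does not cross the half-height level on one side of the peak."""

    def __init__(self, side: str):
        self.side = side
        super().__init__(f"output does not fall below half height on the {side} side")
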