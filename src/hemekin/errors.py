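"""Exception hierarchy for kinetics and fitting failures."""


class HemekinError(Exception):
    """Base class for all package-specific errors."""


class NoGeminateChannelError(HemekinError):
    """Raised when F_gem = 0 makes the solvent rebinding rate k_-2 unidentifiable."""


class LockedHexacoordinationError(HemekinError):
    """Raised when k_off,H = 0, so the His binding equilibrium K_H is undefined."""


class FitConvergenceError(HemekinError):
    """Raised when a nonlinear fit fails to converge from every starting point."""


class AmbiguousAssignmentError(HemekinError):
    """Raised when phase classification cannot uniquely label fitted components."""

    def __init__(self, message: str, candidates=None):
        super().__init__(message)
        self.candidates = candidates or []


class UnderdeterminedError(HemekinError):
    """Raised when the data cannot constrain the requested estimate."""


class UnresolvablePhasesWarning(UserWarning):
    """Emitted when two fitted relaxation rates are too close to separate."""


class UnidentifiableParameterWarning(UserWarning):
    """Emitted when a fitted parameter's standard error exceeds its value."""
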