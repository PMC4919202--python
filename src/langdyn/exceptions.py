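"""Exception hierarchy shared across the package."""


class LangdynError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(LangdynError, ValueError):
    """A parameter set or input object violates its schema."""


class RangeError(LangdynError, ValueError):
    """A numeric parameter lies outside its admissible range."""


class SingularStateError(LangdynError, ValueError):
    """A shared-capacity denominator K - u vanishes at a state that needs it."""


class DegenerateDenominatorError(LangdynError, ZeroDivisionError):
    """The interior-equilibrium denominator is (numerically) zero."""


class BoundaryCaseError(LangdynError, ValueError):
    """Parameters sit exactly on a case boundary the analysis splits on."""


class ConfigurationError(LangdynError, ValueError):
    """A simulation configuration is inconsistent (e.g. unstable time step)."""


class DivergenceError(LangdynError, FloatingPointError):
    """The explicit time stepper produced NaN/overflow or a large negative value."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step
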