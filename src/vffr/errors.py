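"""Exception types shared across the package."""


class VFFRError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(VFFRError, ValueError):
    """A parameter violates its physiological or mathematical domain."""


class SingularSystemError(VFFRError, ValueError):
    """A characterization system has no unique solution (e.g. duplicate flows)."""


class NumericalInstabilityError(VFFRError, RuntimeError):
    """A state variable became non-finite during time integration."""


class DegenerateOutputError(VFFRError, ValueError):
    """A statistic is undefined because the model output has zero variance."""
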