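"""Exception types shared across the package."""


class LagoonError(Exception):
    """Base class for all package errors."""


class ParameterError(LagoonError, ValueError):
    """A physically invalid or inconsistent input parameter."""


class ConfigurationError(LagoonError, ValueError):
    """A structurally valid input that cannot produce a trustworthy result
    (e.g. a spatial grid too coarse for the predicted decay length)."""


class NumericalError(LagoonError, RuntimeError):
    """Solver failure detected after the fact (divergence, broken mass balance)."""


class ConvergenceError(LagoonError, RuntimeError):
    """An iterative fit failed to converge after all restarts."""
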