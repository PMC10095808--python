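"""Exception hierarchy for rootniche."""


class RootNicheError(Exception):
    """Base class for all rootniche errors."""


class InvalidParameterError(RootNicheError, ValueError):
    """A kinetic parameter violates its domain (negative rate, K <= 0, n < 1, ...)."""


class UnsupportedVariantError(RootNicheError, ValueError):
    """Unknown model-variant or mutant tag."""


class MissingParameterError(RootNicheError, KeyError):
    """A required named parameter is absent from the parameter set."""

    def __init__(self, names):
        self.names = tuple(names)
        super().__init__(f"missing required parameter(s): {', '.join(self.names)}")


class DimensionError(RootNicheError, ValueError):
    """State-vector length does not match the model."""


class RuleViolationError(RootNicheError, ValueError):
    """A division rule was applied to an agent that cannot divide."""


class ConfigurationError(RootNicheError, ValueError):
    """Inconsistent run configuration (empty free-parameter list, bad rules, ...)."""


class IntegrationFailureError(RootNicheError, RuntimeError):
    """The ODE solver failed; carries the last successfully reached time."""

    def __init__(self, message, last_time=None):
        self.last_time = last_time
        super().__init__(message)


class CalibrationError(RootNicheError, RuntimeError):
    """No feasible division thresholds exist for the given trajectory."""


class IncompleteGridError(RootNicheError, ValueError):
    """A time-course table is missing cells of the 8-h grid."""


class InvalidContingencyError(RootNicheError, ValueError):
    """Overlap counts are mutually inconsistent (k > min(nA, nB), nA > N, ...)."""
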