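"""Exception hierarchy shared across the package."""


class SwaymetricsError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SwaymetricsError, ValueError):
    """A file does not conform to the expected dialect (missing column, bad header)."""


class DataError(SwaymetricsError, ValueError):
    """Input data violate a precondition (non-uniform time base, too short, empty)."""


class ParameterError(SwaymetricsError, ValueError):
    """An analysis parameter is out of its valid range."""


class FitError(SwaymetricsError, ValueError):
    """A regression cannot be performed (too few points, nonpositive values on a log axis)."""


class NumericalError(SwaymetricsError, ArithmeticError):
    """A numerical cross-check failed beyond tolerance."""


class PairingError(SwaymetricsError, ValueError):
    """Subjects are not present in both conditions of a paired design."""


class InstabilityError(SwaymetricsError, RuntimeError):
    """The simulated pendulum diverged for the given parameters."""


class SignalError(SwaymetricsError, ValueError):
    """A controller input sample is non-finite."""
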