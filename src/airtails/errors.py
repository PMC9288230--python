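"""Exception hierarchy shared across the package."""


class AirTailsError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(AirTailsError, ValueError):
    """A distribution parameter is outside its admissible domain."""


class DataError(AirTailsError, ValueError):
    """Input data violate a precondition (too few points, degenerate, ...)."""


class FitError(AirTailsError, RuntimeError):
    """A maximum-likelihood fit could not be carried out."""


class ConvergenceError(FitError):
    """The optimiser terminated without reaching its convergence criterion."""


class TailError(AirTailsError, ValueError):
    """Tail extraction produced an empty or invalid tail."""


class QCFailedError(AirTailsError, RuntimeError):
    """A site failed quality control and must not be fitted."""


class FormatError(AirTailsError, ValueError):
    """A CSV input does not conform to the expected schema."""
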