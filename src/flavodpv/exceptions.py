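"""Exception hierarchy for flavodpv."""


class FlavodpvError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(FlavodpvError, ValueError):
    """A physical parameter is outside its valid domain (e.g. T <= 0, n <= 0)."""


class InvalidInputError(FlavodpvError, ValueError):
    """Input data violates a precondition (empty grid, non-monotone potentials...)."""


class FormatError(FlavodpvError, ValueError):
    """A data file is malformed or misses a mandatory header key."""


class UnderdeterminedError(FlavodpvError, ValueError):
    """Baseline windows contain too few samples for the requested model."""


class ConvergenceError(FlavodpvError, RuntimeError):
    """An iterative fit failed to converge; carries the last iterate.

    Attributes
    ----------
    last_iterate : object
        Parameter vector (or fit object) at the point of failure.
    """

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class InsufficientDataError(FlavodpvError, ValueError):
    """Too few data points for the requested estimator."""


class TraceTooShortError(FlavodpvError, ValueError):
    """A current trace does not extend far enough past an event."""


class UndefinedEnhancementError(FlavodpvError, ValueError):
    """Pre-addition current does not exceed background; enhancement undefined."""
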