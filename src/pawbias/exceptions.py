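"""Exception hierarchy.

``ValidationError`` covers malformed configuration or arguments;
``DataError`` covers inputs that are structurally valid but cannot be
analysed (unscorable sessions, untrackable videos, degenerate variance).
The CLI maps them to exit codes 2 and 3 respectively.
"""


class PawbiasError(Exception):
    """Base class for all package errors."""


class ValidationError(PawbiasError):
    """Invalid configuration, parameters, or file structure."""


class DataError(PawbiasError):
    """Structurally valid input that cannot be analysed."""


class UnscorableSessionError(DataError):
    """A paw-event session with zero usable reaches."""


class DegenerateVarianceError(DataError):
    """A t-test input with zero variance; surfaced instead of returning inf."""


class UntrackableVideoError(DataError):
    """More than half of a bodypart's frames fall below the likelihood threshold."""


class ConvergenceError(DataError):
    """EM failed to converge; carries the log-likelihood trace."""

    def __init__(self, message, loglik_trace=None):
        super().__init__(message)
        self.loglik_trace = list(loglik_trace) if loglik_trace is not None else []
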