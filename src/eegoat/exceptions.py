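"""Exception hierarchy shared across the package."""


class EegoatError(Exception):
    """Base class for all package errors."""


class ValidationError(EegoatError, ValueError):
    """An input violates a documented precondition or invariant."""


class ParseError(EegoatError, ValueError):
    """A plain-text channel file contains a non-numeric line."""


class FormatError(EegoatError, ValueError):
    """A CSV feature matrix does not have the expected header/columns."""


class CapabilityError(EegoatError, RuntimeError):
    """A delegated backend (e.g. the SVM implementation) is unavailable."""


class ConvergenceError(EegoatError, RuntimeError):
    """An iterative fit failed to reach tolerance within its iteration cap.

    Carries the last iterate and diagnostics so callers can inspect it.
    """

    def __init__(self, message, *, last_iterate=None, diagnostics=None):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.diagnostics = diagnostics or {}
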