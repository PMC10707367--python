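"""Exception hierarchy shared across the package."""


class HDLTurnoverError(Exception):
    """Base class for all package errors."""


class ValidationError(HDLTurnoverError, ValueError):
    """Input violates a documented precondition or data contract."""


class DomainError(HDLTurnoverError, ValueError):
    """Mathematically undefined request (e.g. trapped-tracer FCR)."""


class FittingError(HDLTurnoverError, RuntimeError):
    """No optimizer start converged; carries the best diagnostics seen."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics
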