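"""Exception hierarchy shared across the package."""


class PhenoblupError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PhenoblupError, ValueError):
    """A configuration value is invalid or infeasible."""


class StructuralError(PhenoblupError, ValueError):
    """Inputs are structurally inconsistent (shapes, maps, states)."""


class KeyedError(PhenoblupError, KeyError):
    """A referenced entity (line, hybrid, parent) is unknown.

    Carries the offending keys in ``keys``.
    """

    def __init__(self, message: str, keys=()):
        super().__init__(message)
        self.keys = list(keys)

    def __str__(self) -> str:  # KeyError quotes its arg; keep plain message
        return self.args[0]


class ConvergenceError(PhenoblupError, RuntimeError):
    """An iterative fit failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace
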