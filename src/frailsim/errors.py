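"""Exception hierarchy shared across the package."""


class FrailsimError(Exception):
    """Base class for all package errors."""


class InvalidInputError(FrailsimError, ValueError):
    """Raised when caller-supplied data violates a precondition."""


class ConfigurationError(FrailsimError, ValueError):
    """Raised when a configuration object is internally inconsistent."""


class StateError(FrailsimError, RuntimeError):
    """Raised when an operation is applied to an object in the wrong state."""


class EstimationError(FrailsimError, RuntimeError):
    """Raised when model fitting fails (degenerate data, separation, non-convergence)."""
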