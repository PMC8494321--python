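"""Exception types shared across the package."""


class NvugreyError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NvugreyError):
    """A parameter set or pipeline configuration is incomplete or invalid."""


class NumericalDomainError(NvugreyError):
    """A model evaluation produced a non-finite value.

    Carries the name of the offending equation/state where known.
    """

    def __init__(self, message, equation=None):
        super().__init__(message)
        self.equation = equation


class IntegrationError(NvugreyError):
    """ODE integration failed; ``last_time`` is the last valid solver time."""

    def __init__(self, message, last_time=None):
        super().__init__(message)
        self.last_time = last_time


class InstabilityError(NvugreyError):
    """A trajectory or candidate model violated a stability bound."""


class ValidationError(NvugreyError):
    """User-supplied data violated a precondition (lengths, signs, bands...)."""
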