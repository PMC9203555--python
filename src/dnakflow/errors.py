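"""Exception hierarchy for dnakflow.

Every anticipated failure mode raises a subclass of :class:`DnakflowError`
so callers can catch pipeline problems separately from programming errors.
"""


class DnakflowError(Exception):
    """Base class for all dnakflow errors."""


class ValidationError(DnakflowError, ValueError):
    """An input violates a documented precondition."""


class IntegrationError(DnakflowError):
    """The kinetic ODE solver failed; message names the time reached."""


class InsufficientDataError(DnakflowError):
    """Too few data points for the requested fit or statistic."""


class UndefinedCorrelationError(DnakflowError):
    """A rank correlation is undefined (zero rank variance)."""


class AlignmentError(DnakflowError):
    """Two keyed collections could not be matched; message lists the keys."""


class EmptySampleError(DnakflowError):
    """A gated sample retained zero events; message names the sample."""


class GrowthFitError(DnakflowError):
    """Logistic growth fitting failed or the curve is not fittable."""


class ConfigError(DnakflowError):
    """A pipeline configuration is inconsistent or incomplete."""
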