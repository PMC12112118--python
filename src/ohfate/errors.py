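"""Exception hierarchy shared across the package."""


class OhfateError(Exception):
    """Base class for all package-specific errors."""


class ContractViolation(OhfateError, ValueError):
    """An argument breaks a documented precondition (dimension, sign, range)."""


class DomainError(OhfateError, ValueError):
    """A time value lies outside the fitted validity domain of a profile."""


class EstimationError(OhfateError, RuntimeError):
    """A regression or optimisation problem is ill-posed or failed."""


class IntegrationError(OhfateError, RuntimeError):
    """The ODE solver failed or produced a trajectory violating mass balance."""


class ParseError(OhfateError, ValueError):
    """A data file could not be parsed; message names the offending row/column."""


class ConfigError(OhfateError, ValueError):
    """A scenario configuration file is invalid."""
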