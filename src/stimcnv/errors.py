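"""Exception hierarchy shared across the package."""


class StimCNVError(Exception):
    """Base class for all package errors."""


class ConfigurationError(StimCNVError, ValueError):
    """A configuration value or key is invalid or unknown."""


class ParameterError(StimCNVError, ValueError):
    """A model parameterisation violates its invariants."""


class DomainError(StimCNVError, ValueError):
    """An input lies outside the domain of an operation."""


class InputError(StimCNVError, ValueError):
    """Malformed user-supplied data (tables, shares, files)."""


class StateError(StimCNVError, RuntimeError):
    """An operation was applied to an object in an invalid state."""


class UndefinedTestError(StimCNVError, ValueError):
    """A statistical test is undefined for the given counts (e.g. zero expectation)."""
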