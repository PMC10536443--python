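"""Exception types shared across the package."""


class PhotoFvCBError(Exception):
    """Base class for package errors."""


class DomainError(PhotoFvCBError, ValueError):
    """An input lies outside the physical domain of an operation."""


class ParameterError(PhotoFvCBError, ValueError):
    """A parameter value violates its invariant."""


class ConsistencyError(PhotoFvCBError, ValueError):
    """Inputs violate a structural model constraint (e.g. W > Wj)."""


class SolverError(PhotoFvCBError, RuntimeError):
    """A steady-state solver could not bracket or locate a root."""


class FitError(PhotoFvCBError, RuntimeError):
    """A least-squares fit failed or the problem is under-determined."""


class ConfigError(PhotoFvCBError, ValueError):
    """A configuration file contains an unknown key or invalid value."""
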