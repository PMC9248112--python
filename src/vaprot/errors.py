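"""Exception hierarchy shared across the package."""


class VaprotError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(VaprotError):
    """A configuration value is outside its declared domain."""


class DataError(VaprotError):
    """Input data violate a structural contract (bad value, bad column, duplicate key)."""


class InsufficientDataError(VaprotError):
    """Too few samples/pairs/participants to run the requested computation."""


class UsageError(VaprotError):
    """An operation was called out of order or with an incompatible object state."""


class FitError(VaprotError):
    """A model fit failed for a structural reason (rank deficiency, collinearity)."""
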