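"""Exception hierarchy shared across the package."""


class CemRadialError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CemRadialError):
    """Raised when a configuration object violates its invariants."""


class DataError(CemRadialError):
    """Raised when input data are malformed or internally inconsistent."""


class InsufficientDataError(DataError):
    """Raised when a filtering or modelling step is left with too few cases."""


class DegenerateInputError(CemRadialError):
    """Raised for inputs on which the requested quantity is undefined."""
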