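"""Exception hierarchy shared across the package."""


class MasafortError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MasafortError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class DataError(MasafortError, ValueError):
    """Malformed or inconsistent input data."""


class DomainError(MasafortError, ValueError):
    """An argument outside the mathematical domain of an operation."""


class ModelError(MasafortError, RuntimeError):
    """The usual-intake model cannot be fitted from the data provided."""
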