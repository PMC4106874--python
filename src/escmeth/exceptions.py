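"""Exception types shared across the package."""


class EscmethError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(EscmethError, ValueError):
    """A configuration object or parameter value is invalid."""


class DataValidationError(EscmethError, ValueError):
    """An input table violates the format or consistency contract."""
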