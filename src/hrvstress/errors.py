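"""Exception hierarchy used across the package."""


class HRVStressError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HRVStressError, ValueError):
    """A file or matrix does not conform to the expected format."""


class ConfigError(HRVStressError, ValueError):
    """A configuration value is missing or out of range."""


class InputError(HRVStressError, ValueError):
    """An input signal or sequence violates a precondition."""
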