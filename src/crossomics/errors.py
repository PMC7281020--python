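"""Exception types shared across the package."""


class CrossOmicsError(Exception):
    """Base class for all package errors."""


class InputError(CrossOmicsError):
    """A malformed input table or record."""


class ConfigurationError(CrossOmicsError):
    """An invalid parameter or run configuration."""
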