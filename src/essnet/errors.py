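"""Exception types shared across the package."""


class EssnetError(Exception):
    """Base class for all package errors."""


class ConfigError(EssnetError):
    """Invalid configuration value or unknown configuration key."""


class GenerationError(EssnetError):
    """The synthetic-data generator cannot honour the requested parameters."""


class InputError(EssnetError):
    """An input table violates its contract (impossible counts, bad ids...)."""


class InsufficientDataError(EssnetError):
    """A statistical comparison was requested on groups too small to test."""
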