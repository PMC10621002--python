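"""Exception hierarchy shared by all magcoex modules."""


class MagcoexError(Exception):
    """Base class for all package errors."""


class FormatError(MagcoexError):
    """A file does not conform to the expected tabular dialect."""


class ValidationError(MagcoexError):
    """A parsed record violates a field invariant."""


class ConfigError(MagcoexError):
    """An invalid configuration (e.g. overlapping planted blocks)."""


class UsageError(MagcoexError):
    """An operation was called with arguments outside its contract."""
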