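"""Exception types shared across the package."""


class OostageError(Exception):
    """Base class for all package errors."""


class ConfigError(OostageError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class InsufficientDataError(OostageError, ValueError):
    """A computation was requested on data that cannot support it."""


class FormatError(OostageError, ValueError):
    """A malformed input file; the message carries the line number where known."""
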