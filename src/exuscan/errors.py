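"""Exception hierarchy."""


class ExuscanError(Exception):
    """Base class for all package errors."""


class InputError(ExuscanError, ValueError):
    """Bad input data: unreadable files, out-of-bounds coordinates, shape mismatches."""


class ConfigError(ExuscanError, ValueError):
    """Invalid configuration values."""
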