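"""Exception hierarchy shared across the pipeline."""


class ContrpError(Exception):
    """Base class for all package errors."""


class FormatError(ContrpError):
    """A recording directory or config file is structurally malformed."""


class DataError(ContrpError):
    """Input data violates a precondition (bad values, wrong shapes, missing class)."""


class ConfigError(ContrpError):
    """A configuration value is invalid or inconsistent."""


class DegenerateInputError(DataError):
    """Input is degenerate for the requested operation (e.g. constant signal to znorm)."""
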