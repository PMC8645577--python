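"""Exception hierarchy shared across the package."""


class MicrostatesError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MicrostatesError, ValueError):
    """Input file or container does not match the declared structure."""


class DataError(MicrostatesError, ValueError):
    """Data content violates a precondition (too short, all rejected, ...)."""


class ParameterError(MicrostatesError, ValueError):
    """A user-supplied parameter is outside its valid range."""
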