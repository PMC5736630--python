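"""Exception hierarchy shared across the package."""


class MicrorheoError(Exception):
    """Base class for all package errors."""


class ParameterError(MicrorheoError, ValueError):
    """A physical or numerical parameter is out of its valid range."""


class AnalysisError(MicrorheoError, ValueError):
    """An analysis step received data it cannot process (e.g. too few points)."""


class InputError(MicrorheoError, ValueError):
    """A required input file or field is missing or malformed."""


class CorruptFileError(InputError):
    """A file exists but cannot be decoded (e.g. truncated TIFF)."""


class ConfigError(MicrorheoError, ValueError):
    """A run configuration contains unknown or invalid keys."""
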