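"""Exception hierarchy shared across the package."""


class MfocnnError(Exception):
    """Base class for package-specific errors."""


class ConfigurationError(MfocnnError, ValueError):
    """Raised for invalid optimizer, network or run configuration."""


class DataError(MfocnnError, ValueError):
    """Raised for malformed or inconsistent input data."""


class UndefinedMetricError(MfocnnError, ValueError):
    """Raised when a requested score is mathematically undefined."""
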