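"""Exception types shared across the package."""


class FtqcError(Exception):
    """Base class for package errors."""


class ConfigurationError(FtqcError, ValueError):
    """Invalid configuration value."""


class DataError(FtqcError, ValueError):
    """Malformed or inconsistent input data."""


class InsufficientDataError(FtqcError, ValueError):
    """Too few rows/samples/subsets for the requested computation."""


class SingularFitError(FtqcError, ValueError):
    """Design matrix is degenerate (zero variance or collinear)."""
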