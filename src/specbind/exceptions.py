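"""Exception hierarchy shared across the package."""


class SpecBindError(Exception):
    """Base class for all package-specific errors."""


class RangeError(SpecBindError, ValueError):
    """Requested wavelengths or windows fall outside the available data."""


class DataError(SpecBindError, ValueError):
    """Input data violate a model precondition (e.g. non-positive intensities)."""


class FitError(SpecBindError, RuntimeError):
    """A regression could not be performed (too few usable points)."""


class ConfigError(SpecBindError, ValueError):
    """Invalid configuration for a generator or pipeline stage."""


class AnalysisError(SpecBindError, RuntimeError):
    """An analysis step could not produce a result (e.g. no peak found)."""
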