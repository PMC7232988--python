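"""Exception hierarchy."""


class CoexmapError(Exception):
    """Base class for package errors."""


class ConfigurationError(CoexmapError):
    """Invalid configuration value or combination."""


class GeometryError(CoexmapError):
    """Mismatched or degenerate site geometry."""


class IOFormatError(CoexmapError):
    """Malformed or inconsistent input file."""


class FitError(CoexmapError):
    """Variogram model fitting failed on all starts."""


class NumericalError(CoexmapError):
    """Linear-algebra failure that jitter could not repair."""
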