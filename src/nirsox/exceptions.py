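"""Exception hierarchy shared by all nirsox modules."""


class NirsoxError(Exception):
    """Base class for all errors raised by nirsox."""


class ValidationError(NirsoxError):
    """Invalid configuration, geometry, or physically impossible parameters."""


class DataError(NirsoxError):
    """Malformed or physically impossible input data (e.g. non-positive intensity)."""


class NumericalError(NirsoxError):
    """Numerically degenerate problem (rank deficiency, degenerate time axis)."""


class InsufficientStatisticsError(NirsoxError):
    """Too few detected photons (or samples) to form a reliable statistic."""
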