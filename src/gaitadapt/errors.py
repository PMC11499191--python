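"""Exception hierarchy shared across the package."""


class GaitAdaptError(Exception):
    """Base class for all package errors."""


class ValidationError(GaitAdaptError, ValueError):
    """Invalid argument or contract violation detected before computation."""


class EmptySeriesError(GaitAdaptError):
    """An operation produced or received a series with no usable events."""


class DegenerateStatisticError(GaitAdaptError):
    """A statistic is undefined for the given data (e.g. constant residuals,
    a perfect fit with zero residual sum of squares, or all-zero paired
    differences)."""
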