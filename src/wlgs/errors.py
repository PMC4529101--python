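"""Exception types shared across the WLGS pipeline."""


class WLGSError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(WLGSError):
    """Invalid configuration value or unknown option (e.g. log dialect)."""


class EmptyLogError(WLGSError):
    """A sensor log contained no valid detection records."""


class AlignmentError(WLGSError):
    """Two series/tensors do not share the same epoch grid."""


class EmptyDayError(WLGSError):
    """A measurement day has no usable epochs (T = 0)."""


class InsufficientDataError(WLGSError):
    """Too few observations for the requested operation."""


class ExtrapolationError(WLGSError):
    """A value was requested outside the observed day range."""


class ConstantSeriesError(WLGSError):
    """A correlation/trend is undefined because a series has zero variance."""


class InsufficientOverlapError(WLGSError):
    """Two series overlap on too few days to correlate."""


class FitError(WLGSError):
    """No candidate time-series model converged."""


class EmptyReportError(WLGSError):
    """Video/localization comparison has no overlapping coverage."""
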