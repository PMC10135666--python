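"""Exception hierarchy shared across the pipeline stages."""


class HsiError(Exception):
    """Base class for all errors raised by this package."""


class InvalidCountError(HsiError, ValueError):
    """A larval count is negative (counts are individuals caught)."""


class InvalidVolumeError(HsiError, ValueError):
    """A filtered-water volume is zero or negative."""


class OutOfDomainError(HsiError, ValueError):
    """A station position falls outside the analysis grid."""


class GridMismatchError(HsiError, ValueError):
    """Fields expected to share a grid do not."""


class MissingFieldError(HsiError, LookupError):
    """No environmental field available for a requested month/variable."""


class DegenerateMonthError(HsiError, ValueError):
    """All densities in a month are zero, so SI = Y / Y_max is undefined."""


class UnderdeterminedFitError(HsiError, ValueError):
    """Too few samples or distinct abscissae to fit the 2-parameter curve."""


class FitFailureError(HsiError, RuntimeError):
    """Nonlinear least squares did not converge."""


class InvalidCurveError(HsiError, ValueError):
    """A suitability curve violates its contract (e.g. curvature A >= 0)."""


class InsufficientDataError(HsiError, ValueError):
    """Not enough observations for the requested statistic or split."""


class ConfigurationError(HsiError, ValueError):
    """Invalid or inconsistent configuration (thresholds, months, grids)."""


class InputError(HsiError, ValueError):
    """Malformed runtime input (mismatched lengths, empty vectors, ...)."""


class MissingArtifactError(HsiError, FileNotFoundError):
    """A pipeline stage requires an artifact a previous stage has not written."""
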