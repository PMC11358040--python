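"""Exception hierarchy for the screening pipeline.

Every stage raises a subclass of :class:`TrsaxsError` so drivers can
flag-and-continue per sample without catching bare ``Exception``.
"""


class TrsaxsError(Exception):
    """Base class for all package errors."""


class ParseError(TrsaxsError):
    """Malformed profile or table text (bad token, non-monotone q, ...)."""


class SchemaError(TrsaxsError):
    """Manifest/table violates the required column or uniqueness schema."""


class GridError(TrsaxsError):
    """Curves do not share a q grid where an identical grid is required."""


class RangeError(TrsaxsError):
    """Requested q values fall outside the available range (no extrapolation)."""


class AlignmentError(TrsaxsError):
    """Frame times or trace lengths do not line up within tolerance."""


class RatioError(TrsaxsError):
    """Non-positive intensity inside the ratio window."""


class WindowError(TrsaxsError):
    """Analysis window too narrow (not enough points or bins)."""


class FitError(TrsaxsError):
    """A model fit failed to converge or is ill-posed on these data."""


class DataError(TrsaxsError):
    """Input values are unusable (non-finite, all non-positive, ...)."""


class ConfigError(TrsaxsError):
    """Invalid simulation or pipeline configuration."""
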