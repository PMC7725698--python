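"""Typed errors raised across the package.

Degenerate inputs raise rather than returning NaN so that batch pipelines
fail loudly instead of silently propagating undefined measures.
"""


class GazeNoiseError(Exception):
    """Base class for all package errors."""


class InvalidSegmentError(GazeNoiseError, ValueError):
    """Segment is malformed: too short, non-finite, or mismatched lengths."""


class DegenerateSegmentError(GazeNoiseError, ValueError):
    """Segment has a rank-deficient or zero-variance covariance structure."""


class UndefinedSignalTypeError(DegenerateSegmentError):
    """Signal type is undefined because the segment has zero dispersion."""


class MappingRangeError(GazeNoiseError, ValueError):
    """Requested signal-type value lies outside the achievable range."""


class ConfigError(GazeNoiseError, ValueError):
    """Inconsistent or missing configuration (columns, units, parameters)."""


class ParseError(GazeNoiseError, ValueError):
    """Input file violates the expected gaze-recording layout."""
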