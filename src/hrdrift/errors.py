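"""Exception hierarchy for hrdrift.

All domain errors derive from :class:`HrDriftError`, itself a ``ValueError``,
so callers can catch either the package root or the builtin.
"""


class HrDriftError(ValueError):
    """Root of all hrdrift domain errors."""


class InvalidProfileError(HrDriftError):
    """Subject profile fields are inconsistent or out of range."""


class EmptyInputError(HrDriftError):
    """An operation that needs samples received none."""


class InvalidBoundsError(HrDriftError):
    """Heart-rate bounds are degenerate (hr_max <= hr_rest or non-positive)."""


class DegenerateNormalizationError(HrDriftError):
    """Normalization offset equals the end value: zero delta."""


class ProtocolMismatchError(HrDriftError):
    """A protocol window cannot be resolved from the session's segments."""


class InvalidPolygonError(HrDriftError):
    """Fewer than three vertices were supplied for an area computation."""


class DegenerateTestError(HrDriftError):
    """Paired differences have zero variance; the t statistic is undefined."""


class SeriesParseError(HrDriftError):
    """A CSV input violated the series/segments schema; message names the line."""
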