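"""Exception hierarchy for aquacore.

All domain errors derive from :class:`AquacoreError` so callers can catch
pipeline failures without intercepting programming errors.
"""


class AquacoreError(Exception):
    """Base class for all aquacore domain errors."""


class ValidationError(AquacoreError, ValueError):
    """An input table or metadata frame violates a structural invariant."""


class DegenerateCommunityError(AquacoreError):
    """All sample pairs in a group are identical (total dissimilarity zero)."""


class DegenerateSeriesError(AquacoreError):
    """A series is constant, so moment-based statistics are undefined."""


class InsufficientObservationsError(AquacoreError):
    """Too few observations for the requested statistic."""


class InsufficientTimepointsError(AquacoreError):
    """A site-year has fewer sampling dates than the statistic requires."""


class UndefinedDissimilarityError(AquacoreError):
    """Bray-Curtis dissimilarity requested for two all-zero vectors."""


class UndefinedCVError(AquacoreError):
    """Coefficient of variation requested for a zero-mean series."""
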