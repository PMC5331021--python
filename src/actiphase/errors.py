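"""Exception hierarchy for the actiphase pipeline.

Every stage raises a subclass of :class:`ActiphaseError` so callers can
distinguish pipeline failures from programming errors.
"""


class ActiphaseError(Exception):
    """Base class for all actiphase errors."""


class FormatError(ActiphaseError):
    """A file does not conform to the expected tabular layout."""


class IntegrityError(ActiphaseError):
    """A recording violates the minute-series invariants (gap, duplicate,
    negative count)."""


class InsufficientDataError(ActiphaseError):
    """A day window is too short to contain one full active period."""


class UndefinedFeatureError(ActiphaseError):
    """A feature is mathematically undefined for this segment (zero mean,
    zero variance, or no sample-entropy template matches)."""


class ConfigurationError(ActiphaseError):
    """A run or generator configuration violates its invariants."""


class SingularityError(ActiphaseError):
    """A scatter matrix required by the discriminant analysis is singular.

    Usually means too few cases per predictor; reduce the predictor set or
    pool groups.
    """
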