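"""Exception hierarchy for thalrisk.

Every error raised by the library derives from :class:`ThalriskError`, so
callers can catch a single base class at pipeline boundaries.
"""


class ThalriskError(Exception):
    """Base class for all thalrisk errors."""


class SchemaError(ThalriskError):
    """A cohort file or record does not conform to the feature schema."""


class CohortParseError(ThalriskError):
    """A cell could not be parsed as the declared feature kind."""


class LevelError(ThalriskError):
    """A categorical value lies outside the declared levels."""


class MissingnessError(ThalriskError):
    """Missing values exceed the configured tolerance."""


class ScaleError(ThalriskError):
    """A pairwise judgment is non-positive and therefore off the Saaty scale."""


class AlignmentError(ThalriskError):
    """Two artifacts that must share a feature/criterion set do not."""


class DegenerateLabelError(ThalriskError):
    """A label vector with fewer than two classes was supplied."""


class DegenerateCriterionError(ThalriskError):
    """A decision-matrix criterion has zero range and cannot be scaled."""


class DegenerateCohortError(ThalriskError):
    """All samples coincide, leaving relative closeness undefined."""


class StratificationError(ThalriskError):
    """Stratified folds cannot be formed (a class is smaller than k)."""


class ConsistencyGateError(ThalriskError):
    """Judgments failed the CR < 0.1 gate and no override was given."""


class ConfigError(ThalriskError):
    """Invalid pipeline or stratification configuration."""
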