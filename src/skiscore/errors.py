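"""Exception hierarchy for the skiscore pipeline."""


class SkiScoreError(Exception):
    """Base class for all skiscore errors."""


class FormatError(SkiScoreError):
    """A file does not conform to the documented CSV/JSON schema."""


class EmptyInputError(SkiScoreError):
    """An input file or container holds no usable data."""


class InsufficientDataError(SkiScoreError):
    """Too few samples for the requested operation (e.g. filter warm-up)."""


class InsufficientReferenceError(SkiScoreError):
    """A (style, size) cell holds fewer turns than the configured minimum."""


class EmptyModelError(SkiScoreError):
    """No (style, size) cell reached the minimum reference-turn count."""


class ValidationError(SkiScoreError):
    """A domain invariant is violated (shapes, ranges, orthonormality...)."""


class DimensionError(ValidationError):
    """A vector does not have the expected length (101-point time base)."""


class SchemaVersionError(FormatError):
    """A persisted model declares an unknown schema version."""


class DegenerateModelError(SkiScoreError):
    """A reference PC with non-zero variance fraction has zero score SD."""


class MissingCellError(SkiScoreError):
    """The reference model has no cell for a turn's (style, size)."""


class SegmentRangeError(SkiScoreError):
    """A turn segment lies (partly) outside the covering sensor stream."""


class UndefinedStatisticError(SkiScoreError):
    """A statistic is undefined for the given sample (e.g. zero variance)."""


class ConfigError(SkiScoreError):
    """Invalid configuration value."""
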