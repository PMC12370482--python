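"""Exception hierarchy for the laserlesion pipeline.

Every stage raises a subclass of :class:`LaserLesionError`, so callers can
catch one type at the CLI boundary while tests assert on specific failures.
"""


class LaserLesionError(Exception):
    """Base class for all pipeline errors."""


class InvalidParameterError(LaserLesionError, ValueError):
    """A physical or configuration parameter violates its domain."""


class SchemaError(LaserLesionError):
    """A sidecar/config document is missing or mistypes a required field."""


class FormatError(LaserLesionError):
    """A file on disk does not have the expected structure."""


class DataValidationError(LaserLesionError):
    """File contents parsed but failed a semantic validity check."""


class DegenerateInputError(LaserLesionError):
    """An input image or mask carries no usable signal."""


class NoEdgesError(LaserLesionError):
    """RATS found no significant gradient anywhere: nothing to threshold."""


class EmptyMaskError(LaserLesionError):
    """A mask became (or was) empty where a nonempty one is required."""


class DegenerateMaskError(LaserLesionError):
    """A mask is too small to carry a boundary ring."""


class OutOfFrameError(LaserLesionError):
    """A registered mask does not fit inside the thermal frame."""


class WindowTooShortError(LaserLesionError):
    """The exposure window has too few frames for steady-state averaging."""


class QCError(LaserLesionError):
    """An image failed an automated quality-control gate."""


class SeparationError(LaserLesionError):
    """Complete separation: the probit likelihood has no finite maximum.

    Carries the crossover gap so callers can hand off to deterministic
    threshold detection.
    """

    def __init__(self, msg, max_negative=None, min_positive=None):
        super().__init__(msg)
        self.max_negative = max_negative
        self.min_positive = min_positive


class UnboundedLimitsError(LaserLesionError):
    """Fieller's g >= 1: fiducial limits are unbounded at this level."""


class InvalidComparisonError(LaserLesionError):
    """Two fits cannot be compared (e.g. identical exposure durations)."""


class RankDeficiencyError(LaserLesionError):
    """A regression design matrix is rank deficient."""


class StageError(LaserLesionError):
    """Wraps an error with the pipeline stage where it occurred."""

    def __init__(self, stage, original):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original
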