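"""Exception hierarchy for the quantification pipeline.

Every stage raises a subclass of :class:`MitofluxError`, so callers can
trap pipeline failures distinctly from programming errors.
"""


class MitofluxError(Exception):
    """Base class for all pipeline errors."""


class TraceFormatError(MitofluxError):
    """A trace file is missing required columns or cannot be parsed."""


class TraceValidationError(MitofluxError):
    """A parsed trace violates an invariant (e.g. non-monotonic time)."""


class InsufficientDataError(MitofluxError):
    """Too few samples inside the requested analysis window."""


class SegmentationError(MitofluxError):
    """A required injection event (homogenate, ADP) is absent."""


class RcrUndefinedError(MitofluxError):
    """State-2 flux is non-positive, so the respiratory control ratio
    is undefined."""


class CalibrationError(MitofluxError):
    """A fluorescence calibration is degenerate or has a non-positive
    slope."""


class UndefinedLeakError(MitofluxError):
    """Percent electron leak is undefined because the paired oxygen
    flux is non-positive."""


class NormalizationError(MitofluxError):
    """Normalization to mitochondrial content is undefined (citrate
    synthase rate <= 0)."""


class AssayConfigError(MitofluxError):
    """An enzyme assay configuration is invalid or mismatched."""


class ScoringError(MitofluxError):
    """Invalid input to disease-activity scoring."""


class StatsError(MitofluxError):
    """Invalid input to a group-comparison statistic."""


class SpecError(MitofluxError):
    """A synthetic-data specification is infeasible or invalid."""


class ConfigError(MitofluxError):
    """The pipeline configuration file is invalid."""
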