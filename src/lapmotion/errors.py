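"""Exception hierarchy for the motion-analysis pipeline."""


class LapMotionError(Exception):
    """Base class for all package errors."""


class TrackParseError(LapMotionError):
    """A trajectory file could not be parsed; message names the offending line."""


class TrackValidationError(LapMotionError):
    """A track violates a structural invariant (non-monotonic time, length mismatch...)."""


class ConfigurationError(LapMotionError):
    """Missing or inconsistent configuration (units, infeasible schedules...)."""


class SegmentTooShortError(LapMotionError):
    """A track segment is shorter than the smoothing window; its metrics are undefined."""


class UndefinedMetricError(LapMotionError):
    """A metric has no defined value for this input (e.g. no valid frames)."""


class UnstableAnchorError(LapMotionError):
    """An anchor dwell recording moved too much to define a working-axis endpoint."""


class IntegrityError(LapMotionError):
    """Duplicate or inconsistent rows in an assembled metric table."""


class ConstantMetricError(LapMotionError):
    """A metric with zero spread (NIQR = 0) cannot be robust-normalized."""


class InsufficientInputError(LapMotionError):
    """Too few metrics or samples for the requested multivariate analysis."""
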