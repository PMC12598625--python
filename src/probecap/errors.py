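"""Exception hierarchy."""


class ProbecapError(Exception):
    """Base class for package errors."""


class ValidationError(ProbecapError, ValueError):
    """Invalid user input or configuration."""


class AlignmentShapeError(ValidationError):
    """Ragged multiple alignment."""


class EmptyModelError(ValidationError):
    """Alignment yields no usable match column."""


class CalibrationError(ProbecapError):
    """Null-score distribution could not be fitted."""


class UncalibratedProfileError(ProbecapError):
    """Profile search requested before E-value calibration."""


class InfeasibleTargetError(ValidationError):
    """Requested weighted GC outside the attainable range."""

    def __init__(self, target: float, lo: float, hi: float):
        super().__init__(
            f"target GC {target:g} mol% outside attainable range "
            f"[{lo:g}, {hi:g}] mol%"
        )
        self.target, self.lo, self.hi = target, lo, hi


class PlacementError(ProbecapError):
    """Requested genes do not fit in the genome."""


class InsufficientDataError(ProbecapError):
    """Not enough shared observations for the requested statistic."""


class StageFailure(ProbecapError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
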