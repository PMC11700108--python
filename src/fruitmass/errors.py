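"""Package-wide exception types."""


class FruitmassError(Exception):
    """Base class for all package errors."""


class SpecError(FruitmassError, ValueError):
    """A generation/imaging/run specification violates its invariants."""


class FrameFitError(FruitmassError, ValueError):
    """A rendered object does not fit inside the image frame."""


class SamplingError(FruitmassError, RuntimeError):
    """Rejection sampling exhausted its retry budget (infeasible bounds)."""


class SegmentationError(FruitmassError, RuntimeError):
    """The segmentation chain could not produce a valid fruit mask."""


class DegenerateImageError(SegmentationError):
    """Image has too little chromatic structure to cluster."""


class CalibrationError(FruitmassError, RuntimeError):
    """The calibration square could not be located or measured."""


class FitError(FruitmassError, RuntimeError):
    """A model fit failed (singular system, non-convergence, bad input)."""
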