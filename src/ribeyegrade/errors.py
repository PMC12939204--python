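"""Exception hierarchy for the rib-eye grading pipeline."""


class RibeyeError(Exception):
    """Base class for all errors raised by this package."""


class InputError(RibeyeError):
    """Unreadable, undecodable or otherwise invalid input data."""


class CalibrationError(RibeyeError):
    """Invalid pixel-to-physical scale calibration."""


class DegenerateHistogramError(RibeyeError):
    """Automatic thresholding asked of a single-valued histogram."""


class SegmentationError(RibeyeError):
    """Segmentation produced no usable foreground."""


class MeasurementError(RibeyeError):
    """Morphometric or colorimetric measurement on invalid input."""


class UngradableError(RibeyeError):
    """No grading parameter fell inside the grading table's range."""


class GenerationError(RibeyeError):
    """Synthetic sample generation could not satisfy its target."""


class ConfigError(RibeyeError):
    """Unknown or invalid pipeline configuration key/value."""


class StatsError(RibeyeError):
    """Invalid input to a statistical routine."""
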