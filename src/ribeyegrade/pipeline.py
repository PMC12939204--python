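"""End-to-end convenience: calibrated image in, measurements and grade out."""

from __future__ import annotations

from dataclasses import dataclass

from .config import PipelineConfig
from .grading import GradeResult, GradingTable, grade_sample
from .io_calibration import CalibratedImage
from .measurement import MeasurementRecord, measure_sample
from .segmentation import BinaryMask, segment_marbling, segment_ribeye

__all__ = ["SampleResult", "analyze_sample"]


@dataclass
class SampleResult:
    """Everything the pipeline produced for one sample."""

    record: MeasurementRecord
    grade: GradeResult
    ribeye_mask: BinaryMask
    marbling_mask: BinaryMask


def analyze_sample(
    ci: CalibratedImage,
    config: PipelineConfig | None = None,
    table: GradingTable | None = None,
    sample_id: str = "sample",
) -> SampleResult:
    """Segment, measure and grade one calibrated image.

    Deterministic given image + configuration: segmentation (rib-eye, then
    marbling within it), morphometry and colorimetry, then grading against
    ``table`` (the default thresholds when None) with the configured
    combination strategy.
    """
    config = PipelineConfig.ensure(config)
    ribeye = segment_ribeye(ci, config)
    marbling = segment_marbling(ci, ribeye, config)
    record = measure_sample(ci, ribeye, marbling, config, sample_id=sample_id)
    grade = grade_sample(
        record,
        table=table,
        strategy=config["grading.strategy"],
        clamp_below_scale=config["grading.clamp_below_scale"],
    )
    return SampleResult(record=record, grade=grade, ribeye_mask=ribeye, marbling_mask=marbling)
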