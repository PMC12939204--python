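"""Five-level (A1-A5) grading of rib-eye measurements.

Three parameters are graded against interval thresholds — rib-eye area
(cm^2), marbling percentage, and the red share R/(R + G + B) — and the
three per-parameter grades are combined into one final grade.  Area and
marbling increase with grade; the red ratio decreases (brighter, fattier,
higher-grade cuts are less red).

Default thresholds::

    grade        A1        A2         A3         A4        A5
    area cm^2    40-50     50-60      60-75      75-90     >90
    marbling %   <10       10-30      30-50      50-70     >70
    red ratio    >0.49     0.49-0.47  0.47-0.45  0.45-0.43 <0.43

Printed interval endpoints touch; they are resolved half-open here, lower-
inclusive for the increasing parameters and upper-inclusive for the
decreasing ratio, so a shared endpoint always lands on the lower grade
index (area 50 -> A2, ratio 0.49 -> A2).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .errors import UngradableError

__all__ = [
    "Interval",
    "GradingTable",
    "GradeResult",
    "GRADE_LABELS",
    "PARAMETERS",
    "STRATEGIES",
    "default_grading_table",
    "grade_parameter",
    "combine_grades",
    "grade_values",
    "grade_sample",
]

GRADE_LABELS = ("A1", "A2", "A3", "A4", "A5")
PARAMETERS = ("area_cm2", "marbling_pct", "red_ratio")
STRATEGIES = ("majority_marbling", "marbling_only", "minimum")


@dataclass(frozen=True)
class Interval:
    """A possibly half-open real interval."""

    lo: float
    hi: float
    lo_inclusive: bool = True
    hi_inclusive: bool = False

    def contains(self, value: float) -> bool:
        above = value >= self.lo if self.lo_inclusive else value > self.lo
        below = value <= self.hi if self.hi_inclusive else value < self.hi
        return above and below


@dataclass(frozen=True)
class GradingTable:
    """Per-parameter interval thresholds defining grades A1..A5.

    ``intervals[param][i]`` is the interval for grade index ``i + 1``.
    ``orientation[param]`` records whether the parameter increases
    ("increasing") or decreases ("decreasing") with grade.
    """

    intervals: dict[str, tuple[Interval, ...]]
    orientation: dict[str, str] = field(
        default_factory=lambda: {
            "area_cm2": "increasing",
            "marbling_pct": "increasing",
            "red_ratio": "decreasing",
        }
    )

    def __post_init__(self) -> None:
        for param in PARAMETERS:
            if param not in self.intervals:
                raise ValueError(f"grading table missing parameter {param!r}")
            if len(self.intervals[param]) != len(GRADE_LABELS):
                raise ValueError(f"{param}: expected {len(GRADE_LABELS)} intervals")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "orientation": self.orientation,
            "intervals": {
                param: [
                    {
                        "grade": GRADE_LABELS[i],
                        "lo": iv.lo,
                        "hi": iv.hi,
                        "lo_inclusive": iv.lo_inclusive,
                        "hi_inclusive": iv.hi_inclusive,
                    }
                    for i, iv in enumerate(ivs)
                ]
                for param, ivs in self.intervals.items()
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "GradingTable":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        intervals = {
            param: tuple(
                Interval(
                    lo=item["lo"],
                    hi=item["hi"],
                    lo_inclusive=item["lo_inclusive"],
                    hi_inclusive=item["hi_inclusive"],
                )
                for item in items
            )
            for param, items in payload["intervals"].items()
        }
        return cls(intervals=intervals, orientation=dict(payload["orientation"]))


def default_grading_table() -> GradingTable:
    """The default A1-A5 thresholds with deterministic boundary resolution."""
    return GradingTable(
        intervals={
            "area_cm2": (
                Interval(40.0, 50.0),
                Interval(50.0, 60.0),
                Interval(60.0, 75.0),
                Interval(75.0, 90.0),
                Interval(90.0, math.inf),
            ),
            "marbling_pct": (
                Interval(0.0, 10.0),
                Interval(10.0, 30.0),
                Interval(30.0, 50.0),
                Interval(50.0, 70.0),
                Interval(70.0, 100.0, hi_inclusive=True),
            ),
            "red_ratio": (
                Interval(0.49, 1.0, lo_inclusive=False, hi_inclusive=True),
                Interval(0.47, 0.49, lo_inclusive=False, hi_inclusive=True),
                Interval(0.45, 0.47, lo_inclusive=False, hi_inclusive=True),
                Interval(0.43, 0.45, lo_inclusive=False, hi_inclusive=True),
                Interval(0.0, 0.43, lo_inclusive=False, hi_inclusive=True),
            ),
        }
    )


def grade_parameter(
    value: float, parameter: str, table: GradingTable | None = None
) -> int | None:
    """Grade index 1-5 for one parameter, or None if the value is out of range.

    A rib-eye area below the A1 floor (40 cm^2) is out of range — "below
    scale" — rather than clamped; likewise non-finite values or a ratio
    outside (0, 1].
    """
    if table is None:
        table = default_grading_table()
    if parameter not in table.intervals:
        raise ValueError(f"unknown grading parameter {parameter!r}")
    if not math.isfinite(value) and not (parameter == "area_cm2" and value == math.inf):
        return None
    for i, interval in enumerate(table.intervals[parameter]):
        if interval.contains(value):
            return i + 1
    return None


@dataclass
class GradeResult:
    """Per-parameter grade indices, the combined final grade, and warnings."""

    area_grade: int | None
    marbling_grade: int | None
    ratio_grade: int | None
    final_index: int
    final_grade: str
    strategy: str
    flags: tuple[str, ...] = ()


def combine_grades(
    area_g: int | None,
    marbling_g: int | None,
    ratio_g: int | None,
    strategy: str = "majority_marbling",
) -> tuple[int, tuple[str, ...]]:
    """Combine per-parameter grade indices into one final grade index.

    Strategies:

    * ``majority_marbling`` (default): if at least two in-range parameter
      grades agree, that grade wins; otherwise the marbling grade decides
      (marbling is the single most important quality indicator).
    * ``marbling_only``: the marbling grade alone.
    * ``minimum``: the lowest in-range grade (conservative).

    Out-of-range parameters are flagged and excluded from voting.  A spread
    greater than one grade between in-range parameters sets a
    ``grade_disagreement`` flag.  All parameters out of range raises
    :class:`UngradableError`.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    named = {"area": area_g, "marbling": marbling_g, "ratio": ratio_g}
    flags = tuple(f"out_of_range:{name}" for name, g in named.items() if g is None)
    in_range = [g for g in named.values() if g is not None]
    if not in_range:
        raise UngradableError("all grading parameters out of range")
    if max(in_range) - min(in_range) > 1:
        flags += ("grade_disagreement",)

    if strategy == "marbling_only":
        if marbling_g is None:
            raise UngradableError("marbling grade out of range with strategy=marbling_only")
        return marbling_g, flags
    if strategy == "minimum":
        return min(in_range), flags
    # majority_marbling
    for candidate in set(in_range):
        if in_range.count(candidate) >= 2:
            return candidate, flags
    if marbling_g is not None:
        return marbling_g, flags
    raise UngradableError("no majority and marbling grade out of range")


def grade_values(
    area_cm2: float,
    marbling_pct: float,
    red_ratio: float,
    table: GradingTable | None = None,
    strategy: str = "majority_marbling",
    clamp_below_scale: bool = False,
) -> GradeResult:
    """Grade a raw (area, marbling, ratio) triple."""
    if table is None:
        table = default_grading_table()
    area_g = grade_parameter(area_cm2, "area_cm2", table)
    flags: tuple[str, ...] = ()
    if area_g is None and clamp_below_scale and 0 < area_cm2 < table.intervals["area_cm2"][0].lo:
        area_g = 1
        flags += ("area_clamped_below_scale",)
    marbling_g = grade_parameter(marbling_pct, "marbling_pct", table)
    ratio_g = grade_parameter(red_ratio, "red_ratio", table)
    final_index, combine_flags = combine_grades(area_g, marbling_g, ratio_g, strategy)
    return GradeResult(
        area_grade=area_g,
        marbling_grade=marbling_g,
        ratio_grade=ratio_g,
        final_index=final_index,
        final_grade=GRADE_LABELS[final_index - 1],
        strategy=strategy,
        flags=flags + combine_flags,
    )


def grade_sample(
    record,
    table: GradingTable | None = None,
    strategy: str = "majority_marbling",
    clamp_below_scale: bool = False,
) -> GradeResult:
    """Grade a :class:`~ribeyegrade.measurement.MeasurementRecord`."""
    return grade_values(
        record.area_cm2,
        record.marbling_pct,
        record.red_ratio,
        table=table,
        strategy=strategy,
        clamp_below_scale=clamp_below_scale,
    )
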