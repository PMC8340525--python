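"""Resolve measurements + config into a renderer-independent DisplayModel.

The display links four panels on one shared time axis: the BP plot (goal
bands, the two-line home/office series, LOWESS trend), a data table with one
column per bin, an annotation track on the x-axis, and a medication timeline
with one lane per drug.  Everything a renderer needs — and nothing about
pixels — lives in the DisplayModel, which serializes losslessly to JSON.

Goal classification follows the like-with-like paradigm: a channel is in
range iff its value sits inside the band of matching hue.  Out-of-range
values get no extra plot affordance (no enlarged or recolored markers, no
fills); the table cell is bolded instead, a dual encoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta

from .aggregate import (
    AggregatedPoint,
    BinSchedule,
    NoPoints,
    SegmentStyle,
    aggregate_measurements,
    classify_segments,
    plan_bins,
)
from .model import (
    Annotation,
    BPMeasurement,
    DisplayConfig,
    GoalRange,
    MedicationCourse,
)
from .smooth import SmoothCurve, TooFewPoints, lowess

__all__ = [
    "GoalStatus",
    "classify_goal",
    "DataTableRow",
    "build_data_table",
    "AnnotationMarker",
    "MedicationLane",
    "DisplayModel",
    "build_display_model",
    "round_half_up",
]

GAP_TEXT = "—"  # em dash placeholder for empty bins
Y_PAD = 5.0  # mmHg of headroom above/below bands and data


@dataclass(frozen=True)
class GoalStatus:
    """Per-channel position relative to the goal range (inclusive bounds)."""

    systolic_status: str  # "below" | "in_range" | "above"
    diastolic_status: str

    @property
    def in_range(self) -> bool:
        return (
            self.systolic_status == "in_range"
            and self.diastolic_status == "in_range"
        )


def _status(v: float, low: float, high: float) -> str:
    if v < low:
        return "below"
    if v > high:
        return "above"
    return "in_range"


def classify_goal(sbp: float, dbp: float, goal: GoalRange) -> GoalStatus:
    """Classify one reading against the goal bands, channel by channel.

    Bounds are inclusive: 140/90 against the default 90-140 / 60-90 goal is
    in range for both channels.
    """
    return GoalStatus(
        systolic_status=_status(sbp, goal.sbp_low, goal.sbp_high),
        diastolic_status=_status(dbp, goal.dbp_low, goal.dbp_high),
    )


def round_half_up(v: float) -> int:
    import math

    return int(math.floor(v + 0.5))


@dataclass(frozen=True)
class DataTableRow:
    """One data-table column (one bin): display texts and bold flags.

    A cell is bold when its value is out of range or the point aggregates
    more than one reading.  Empty bins are gap rows with em-dash texts.
    """

    label: str
    systolic_text: str
    diastolic_text: str
    bold_systolic: bool
    bold_diastolic: bool
    gap: bool


def _bin_label(interval: tuple[datetime, datetime]) -> str:
    start, end = interval
    if end - start < timedelta(days=1):
        return start.strftime("%Y-%m-%d %H:%M")
    return start.strftime("%Y-%m-%d")


def build_data_table(
    points: list[AggregatedPoint],
    bins: list[tuple[datetime, datetime]],
    goal: GoalRange,
) -> list[DataTableRow]:
    """One row per bin in window order; empty bins become gap rows."""
    by_index = {p.bin_index: p for p in points}
    rows = []
    for i, interval in enumerate(bins):
        p = by_index.get(i)
        if p is None:
            rows.append(
                DataTableRow(
                    label=_bin_label(interval),
                    systolic_text=GAP_TEXT,
                    diastolic_text=GAP_TEXT,
                    bold_systolic=False,
                    bold_diastolic=False,
                    gap=True,
                )
            )
            continue
        status = classify_goal(p.mean_systolic, p.mean_diastolic, goal)
        rows.append(
            DataTableRow(
                label=_bin_label(interval),
                systolic_text=str(round_half_up(p.mean_systolic)),
                diastolic_text=str(round_half_up(p.mean_diastolic)),
                bold_systolic=status.systolic_status != "in_range"
                or p.is_aggregate,
                bold_diastolic=status.diastolic_status != "in_range"
                or p.is_aggregate,
                gap=False,
            )
        )
    return rows


@dataclass(frozen=True)
class AnnotationMarker:
    """One x-axis marker; same-date annotations stack into one marker."""

    date: date
    texts: tuple[str, ...]


@dataclass(frozen=True)
class MedicationLane:
    """One drug's lane: (start, end, dose) intervals clipped to the window."""

    name: str
    intervals: tuple[tuple[date, date, str], ...]


@dataclass
class DisplayModel:
    """The fully resolved, renderer-independent description of all panels."""

    window: tuple[datetime, datetime]
    schedule: BinSchedule
    bins: list[tuple[datetime, datetime]]
    points: list[AggregatedPoint]
    segments: list[SegmentStyle]
    smooth_systolic: SmoothCurve | None
    smooth_diastolic: SmoothCurve | None
    table: list[DataTableRow]
    annotations: list[AnnotationMarker]
    med_lanes: list[MedicationLane]
    goal: GoalRange
    config: DisplayConfig
    y_domain: tuple[float, float] = (0.0, 0.0)
    rejects: list = field(default_factory=list)


def _y_domain(points: list[AggregatedPoint], goal: GoalRange) -> tuple[float, float]:
    # Bands are never autoscaled away: the axis always contains both goal
    # ranges, padded, plus the data.
    lo = goal.dbp_low
    hi = goal.sbp_high
    for p in points:
        lo = min(lo, p.mean_diastolic)
        hi = max(hi, p.mean_systolic)
    return lo - Y_PAD, hi + Y_PAD


def _clip_courses(
    meds: list[MedicationCourse], start: date, end: date
) -> list[MedicationLane]:
    # Lane per drug name, ordered by each drug's first start date; courses
    # overlapping the window are clipped to it.  Clipping never changes lane
    # assignment because lanes key on the name alone.
    by_name: dict[str, list[MedicationCourse]] = {}
    for c in sorted(meds, key=lambda c: (c.name, c.start)):
        c_end = c.end if c.end is not None else end
        if c_end < start or c.start > end:
            continue
        by_name.setdefault(c.name, []).append(c)
    lanes = sorted(
        by_name.items(), key=lambda kv: (min(c.start for c in kv[1]), kv[0])
    )
    return [
        MedicationLane(
            name=name,
            intervals=tuple(
                (
                    max(c.start, start),
                    min(c.end if c.end is not None else end, end),
                    c.dose,
                )
                for c in courses
            ),
        )
        for name, courses in lanes
    ]


def _stack_annotations(
    annotations: list[Annotation], start: date, end: date
) -> list[AnnotationMarker]:
    by_date: dict[date, list[str]] = {}
    for a in sorted(annotations, key=lambda a: a.date):
        if start <= a.date <= end:
            by_date.setdefault(a.date, []).append(a.text)
    return [
        AnnotationMarker(date=d, texts=tuple(texts))
        for d, texts in sorted(by_date.items())
    ]


def build_display_model(
    measurements: list[BPMeasurement],
    meds: list[MedicationCourse],
    annotations: list[Annotation],
    config: DisplayConfig,
) -> DisplayModel:
    """Run the full pipeline: schedule -> bins -> aggregate -> segments ->
    smooth -> table, then attach the annotation and medication tracks.

    A window with no readings yields a valid empty-plot model (no points, no
    segments, all-gap table).
    """
    start, end = config.window
    schedule, bins = plan_bins(config.window)
    points = aggregate_measurements(measurements, bins)
    try:
        segments = classify_segments(points, len(bins), config.missing_threshold)
    except NoPoints:
        segments = []

    smooth_s = smooth_d = None
    if config.smoothing.enabled and points:
        x = [(p.time - start).total_seconds() / 86400.0 for p in points]
        try:
            smooth_s = lowess(x, [p.mean_systolic for p in points], config.smoothing)
            smooth_d = lowess(x, [p.mean_diastolic for p in points], config.smoothing)
        except TooFewPoints:
            smooth_s = smooth_d = None  # raw line shown at full opacity

    model = DisplayModel(
        window=config.window,
        schedule=schedule,
        bins=bins,
        points=points,
        segments=segments,
        smooth_systolic=smooth_s,
        smooth_diastolic=smooth_d,
        table=build_data_table(points, bins, config.goal),
        annotations=_stack_annotations(annotations, start.date(), end.date()),
        med_lanes=_clip_courses(meds, start.date(), end.date()),
        goal=config.goal,
        config=config,
    )
    model.y_domain = _y_domain(points, config.goal)
    return model
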