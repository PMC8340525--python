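"""Density-scheduled aggregation of BP readings into display bins.

The display comfortably accommodates at most 62 points in the line graph and
its data table, whatever span of time is shown.  A fixed schedule maps the
requested window length to a bin width and a point cap: a 1-day window uses
30-minute bins (<=48 points), a 2-month window daily bins (<=62 points: the
longest 2-month span, July-August, has 62 days), a year weekly bins (a
calendar year touches at most 54 distinct weeks), and so on up to 1-year
bins.  Bins are anchored at the window start rather than the calendar so the
caps hold for arbitrary windows.

Each non-empty bin becomes one plotted point: the arithmetic mean of its
member readings per channel.  A point representing more than one reading gets
no special plot affordance but is bolded in the data table.

Runs of empty bins control the line style: a gap covering more than 10% of
the window's bins is bridged with a dashed segment, smaller gaps are bridged
solid; either way no point is plotted and the data table shows a gap.
"""

from __future__ import annotations

import calendar
import enum
import math
from bisect import bisect_right
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Iterable, Sequence

from .model import BPMeasurement, Source

__all__ = [
    "BinWidth",
    "BinSchedule",
    "SegmentStyle",
    "AggregatedPoint",
    "SCHEDULE",
    "GLOBAL_POINT_CAP",
    "select_bin_schedule",
    "make_bins",
    "plan_bins",
    "aggregate_measurements",
    "classify_segments",
    "NonPositiveWindow",
    "CapExceeded",
    "NoPoints",
]

GLOBAL_POINT_CAP = 62


class NonPositiveWindow(ValueError):
    """Requested display window has zero or negative length."""


class CapExceeded(RuntimeError):
    """A bin grid exceeded its schedule's point cap (internal error)."""


class NoPoints(ValueError):
    """No bin contains any measurement; the plot renders empty."""


@dataclass(frozen=True)
class BinWidth:
    """A bin width: a fixed duration or a whole number of calendar months."""

    amount: int
    unit: str  # "minutes" | "hours" | "days" | "months"

    def __post_init__(self) -> None:
        if self.unit not in ("minutes", "hours", "days", "months"):
            raise ValueError(f"unknown bin unit {self.unit!r}")
        if self.amount <= 0:
            raise ValueError("bin amount must be positive")

    @property
    def is_calendar(self) -> bool:
        return self.unit == "months"

    def as_timedelta(self) -> timedelta:
        if self.is_calendar:
            raise ValueError("calendar-month widths have no fixed duration")
        return timedelta(**{self.unit: self.amount})

    def __str__(self) -> str:
        unit = self.unit if self.amount != 1 else self.unit[:-1]
        return f"{self.amount} {unit}"


def _add_months(dt: datetime, months: int) -> datetime:
    """dt shifted by whole calendar months, day-of-month clamped."""
    y, m = divmod(dt.month - 1 + months, 12)
    year, month = dt.year + y, m + 1
    day = min(dt.day, calendar.monthrange(year, month)[1])
    return dt.replace(year=year, month=month, day=day)


@dataclass(frozen=True)
class BinSchedule:
    """One row of the density schedule."""

    window_label: str
    max_window_days: int  # longest span (in days) this row covers
    bin_width: BinWidth
    max_points: int


# Window label -> (max span in days, bin width, point cap).  Span maxima are
# the worst calendar case: any 2-month period has at most 62 days (July +
# August), any 4-month period 123 days, any 6-month period 184; a calendar
# year has at most 366 days / 54 distinct weeks; 5 consecutive years at most
# 1827 days, and so on.
SCHEDULE: tuple[BinSchedule, ...] = (
    BinSchedule("1 day", 1, BinWidth(30, "minutes"), 48),
    BinSchedule("1 week", 7, BinWidth(3, "hours"), 56),
    BinSchedule("2 weeks", 14, BinWidth(6, "hours"), 56),
    BinSchedule("1 month", 31, BinWidth(12, "hours"), 62),
    BinSchedule("2 months", 62, BinWidth(1, "days"), 62),
    BinSchedule("4 months", 123, BinWidth(2, "days"), 62),
    BinSchedule("6 months", 184, BinWidth(3, "days"), 62),
    BinSchedule("1 year", 366, BinWidth(7, "days"), 54),
    BinSchedule("2 years", 731, BinWidth(14, "days"), 54),
    BinSchedule("5 years", 1827, BinWidth(1, "months"), 60),
    BinSchedule("10 years", 3653, BinWidth(2, "months"), 60),
    BinSchedule("15 years", 5479, BinWidth(4, "months"), 60),
    BinSchedule("30 years", 10958, BinWidth(6, "months"), 60),
    BinSchedule("60 years", 21915, BinWidth(12, "months"), 60),
)


def select_bin_schedule(window: timedelta) -> BinSchedule:
    """Snap a requested window length up to the smallest schedule row >= it.

    A 10-day request therefore uses the 2-week row (6-hour bins, cap 56).
    Windows beyond the last row (60 years) are unsupported.
    """
    if window <= timedelta(0):
        raise NonPositiveWindow(f"window must be positive, got {window}")
    for row in SCHEDULE:
        if window <= timedelta(days=row.max_window_days):
            return row
    raise NonPositiveWindow(
        f"window {window} exceeds the longest supported span "
        f"({SCHEDULE[-1].max_window_days} days)"
    )


def make_bins(
    window: tuple[datetime, datetime], schedule: BinSchedule
) -> list[tuple[datetime, datetime]]:
    """Half-open bin intervals [b0, b1), [b1, b2), ... covering the window.

    Anchored at the window start; the last bin may overhang past the window
    end.  Month-unit widths step calendar months from the start (day-of-month
    clamped).  Raises CapExceeded if the grid would exceed the schedule's
    point cap — unreachable for a schedule chosen by select_bin_schedule
    except in rare leap-edge alignments, which plan_bins absorbs.
    """
    start, end = window
    if not start < end:
        raise NonPositiveWindow("window start must precede window end")
    bounds: list[datetime] = [start]
    if schedule.bin_width.is_calendar:
        k = schedule.bin_width.amount
        i = 1
        while bounds[-1] < end:
            bounds.append(_add_months(start, i * k))
            i += 1
            if len(bounds) - 1 > schedule.max_points:
                raise CapExceeded(schedule.window_label)
    else:
        w = schedule.bin_width.as_timedelta()
        n = math.ceil((end - start) / w)
        if n > schedule.max_points:
            raise CapExceeded(schedule.window_label)
        bounds.extend(start + (i + 1) * w for i in range(n))
    return list(zip(bounds[:-1], bounds[1:]))


def plan_bins(
    window: tuple[datetime, datetime],
) -> tuple[BinSchedule, list[tuple[datetime, datetime]]]:
    """Choose the schedule row for a concrete window and build its bin grid.

    Starts at the snap-up row and advances if calendar-month drift would
    overflow the cap, so the returned grid always respects both the row cap
    and the global 62-point limit.
    """
    start, end = window
    row0 = select_bin_schedule(end - start)
    from_idx = SCHEDULE.index(row0)
    for row in SCHEDULE[from_idx:]:
        try:
            return row, make_bins(window, row)
        except CapExceeded:
            continue
    raise CapExceeded("no schedule row can cover this window")


@dataclass(frozen=True)
class AggregatedPoint:
    """One display point: the mean of every reading in one bin.

    Means are kept unrounded internally; the renderer and data table round to
    the nearest integer.  ``source_symbol`` is circle when the majority of
    member readings are home measurements, square otherwise (ties go to
    square: office readings are staff-validated).
    """

    bin_index: int
    bin_interval: tuple[datetime, datetime]
    mean_systolic: float
    mean_diastolic: float
    n_measurements: int
    source_symbol: str  # "circle_home" | "square_office"

    @property
    def is_aggregate(self) -> bool:
        return self.n_measurements > 1

    @property
    def time(self) -> datetime:
        """Bin midpoint — the point's plotted abscissa."""
        a, b = self.bin_interval
        return a + (b - a) / 2


def aggregate_measurements(
    measurements: Iterable[BPMeasurement],
    bins: Sequence[tuple[datetime, datetime]],
) -> list[AggregatedPoint]:
    """Mean each channel over the readings falling in each half-open bin.

    Readings outside the bin grid are ignored; each in-window reading lands
    in exactly one bin.  Empty bins yield no point.
    """
    if not bins:
        return []
    starts = [b[0] for b in bins]
    grid_end = bins[-1][1]
    members: dict[int, list[BPMeasurement]] = {}
    for m in measurements:
        if m.timestamp < starts[0] or m.timestamp >= grid_end:
            continue
        idx = bisect_right(starts, m.timestamp) - 1
        members.setdefault(idx, []).append(m)
    points = []
    for idx in sorted(members):
        ms = members[idx]
        n = len(ms)
        n_home = sum(1 for m in ms if m.source is Source.HOME)
        points.append(
            AggregatedPoint(
                bin_index=idx,
                bin_interval=bins[idx],
                mean_systolic=sum(m.systolic for m in ms) / n,
                mean_diastolic=sum(m.diastolic for m in ms) / n,
                n_measurements=n,
                source_symbol=(
                    "circle_home" if n_home * 2 > n else "square_office"
                ),
            )
        )
    return points


class LineStyle(str, enum.Enum):
    SOLID = "solid"
    DASHED = "dashed"


@dataclass(frozen=True)
class SegmentStyle:
    """Style of the line segment joining two consecutive plotted points.

    ``span`` holds the two points' bin indices.  A segment bridging a run of
    empty bins longer than threshold x n_bins is dashed, so the amount of
    missing data can be read off the line style even though no points are
    plotted in the gap.
    """

    span: tuple[int, int]
    style: LineStyle


def classify_segments(
    points: Sequence[AggregatedPoint],
    n_bins: int,
    threshold: float = 0.10,
) -> list[SegmentStyle]:
    """Assign solid/dashed styles to the segments between adjacent points.

    For each maximal run of L empty bins between two plotted points, the
    bridging segment is dashed iff L / n_bins > threshold (strict: a run of
    exactly 10% of the bins renders solid).  Adjacent non-empty bins connect
    solid.  Styles depend only on the empty-bin mask, never on the values.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    if not points:
        raise NoPoints("no non-empty bins")
    segments = []
    for a, b in zip(points[:-1], points[1:]):
        run = b.bin_index - a.bin_index - 1
        style = (
            LineStyle.DASHED if run / n_bins > threshold else LineStyle.SOLID
        )
        segments.append(SegmentStyle(span=(a.bin_index, b.bin_index), style=style))
    return segments
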