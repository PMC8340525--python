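"""Domain types and validation shared by every stage of the display pipeline.

A blood-pressure reading is a pair (systolic, diastolic) in mmHg with a
timestamp and a source (home cuff, office, inpatient, ...).  Timestamps are
timezone-naive local clinic time throughout: the display's semantics are
calendar-local, and no DST arithmetic is attempted.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta

__all__ = [
    "Source",
    "AuthorRole",
    "BPMeasurement",
    "GoalRange",
    "MedicationCourse",
    "Annotation",
    "SmoothParams",
    "DisplayConfig",
    "InvalidMeasurement",
    "InvalidCourse",
    "validate_measurement",
    "DEFAULT_GOAL",
    "SYSTOLIC_COLOR",
    "DIASTOLIC_COLOR",
]

# Two-color, colorblind-safe scheme: mint for systolic, cocoa for diastolic.
# Each channel's points/line share a hue with its goal band ("like with like").
SYSTOLIC_COLOR = "#008471"
DIASTOLIC_COLOR = "#9C652B"

# Physiologic plausibility bounds; reject data-entry garbage, not clinical
# judgement.  Configurable via validate_measurement(lo=, hi=).
PRESSURE_LO = 30.0
PRESSURE_HI = 300.0


class InvalidMeasurement(ValueError):
    """A BP reading violating a physiologic or structural invariant."""


class InvalidCourse(ValueError):
    """A medication course whose dates are inconsistent."""


class Source(str, enum.Enum):
    """Where a reading was taken.

    The final display uses only two marker shapes: circles for home
    measurements, squares for everything clinical (office, inpatient, other);
    additional per-source symbols were found to add complexity without value.
    24-h ambulatory readings are mapped to ``home`` at parse time.
    """

    HOME = "home"
    OFFICE = "office"
    INPATIENT = "inpatient"
    OTHER = "other"

    @property
    def marker(self) -> str:
        return "circle_home" if self is Source.HOME else "square_office"


class AuthorRole(str, enum.Enum):
    PATIENT = "patient"
    PROVIDER = "provider"


@dataclass(frozen=True)
class BPMeasurement:
    """One timestamped systolic/diastolic pair.

    ``confirmed`` marks a home cuff whose accuracy and technique were
    validated by clinic staff against office equipment.
    """

    timestamp: datetime
    systolic: float
    diastolic: float
    source: Source = Source.HOME
    confirmed: bool = False


def validate_measurement(
    m: BPMeasurement,
    lo: float = PRESSURE_LO,
    hi: float = PRESSURE_HI,
) -> BPMeasurement:
    """Return ``m`` unchanged if all invariants hold, else raise.

    Invariants: systolic > diastolic, lo <= diastolic < systolic <= hi, and a
    real (finite, minute-resolution representable) timestamp.  Idempotent.
    """
    if not isinstance(m.timestamp, datetime):
        raise InvalidMeasurement(f"unparseable timestamp: {m.timestamp!r}")
    try:
        s = float(m.systolic)
        d = float(m.diastolic)
    except (TypeError, ValueError) as exc:
        raise InvalidMeasurement(f"non-numeric pressure: {exc}") from exc
    if s != s or d != d:  # NaN
        raise InvalidMeasurement("pressure is NaN")
    if s <= d:
        raise InvalidMeasurement(f"systolic <= diastolic ({s:g} <= {d:g})")
    if d < lo or s > hi:
        raise InvalidMeasurement(
            f"out of bounds ({s:g}/{d:g} outside {lo:g}-{hi:g} mmHg)"
        )
    return m


@dataclass(frozen=True)
class GoalRange:
    """Per-patient acceptable bounds for each channel, mmHg.

    Defaults are the shipped all-patient preset (90-140 systolic,
    60-90 diastolic); personalization is a per-config override.  The two
    ranges may overlap numerically.
    """

    sbp_low: float = 90.0
    sbp_high: float = 140.0
    dbp_low: float = 60.0
    dbp_high: float = 90.0

    def __post_init__(self) -> None:
        if not self.sbp_low < self.sbp_high:
            raise ValueError("sbp_low must be < sbp_high")
        if not self.dbp_low < self.dbp_high:
            raise ValueError("dbp_low must be < dbp_high")


DEFAULT_GOAL = GoalRange()


@dataclass(frozen=True)
class MedicationCourse:
    """One drug/dose interval for the medication timeline.

    A dose change is represented as two adjacent courses of the same drug
    (e.g. lisinopril 10 mg then 20 mg); they share a timeline lane.
    ``end=None`` means ongoing.
    """

    name: str
    dose: str
    start: date
    end: date | None = None

    def __post_init__(self) -> None:
        if self.end is not None and self.start > self.end:
            raise InvalidCourse(
                f"{self.name}: start {self.start} after end {self.end}"
            )


@dataclass(frozen=True)
class Annotation:
    """A dated free-text note (lifestyle change, symptom, ...).

    Deliberately minimal: a user only enters a date and the text.
    """

    date: date
    text: str
    author_role: AuthorRole = AuthorRole.PATIENT

    def __post_init__(self) -> None:
        if not self.text or not self.text.strip():
            raise ValueError("annotation text must be non-empty")


@dataclass(frozen=True)
class SmoothParams:
    """LOWESS settings.

    frac
        Fraction of points in each local neighborhood, in (0, 1].  0.30 keeps
        multi-week trend visible at display densities of ~50-62 points.
    robust_iterations
        Bisquare reweighting passes; 2 de-emphasizes outlier readings, which
        is the point of the smoothing layer.
    """

    frac: float = 0.30
    robust_iterations: int = 2
    enabled: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.frac <= 1.0:
            raise ValueError("frac must be in (0, 1]")
        if self.robust_iterations < 0:
            raise ValueError("robust_iterations must be >= 0")


def _hex_color(c: str) -> str:
    if (
        not isinstance(c, str)
        or len(c) != 7
        or c[0] != "#"
        or any(ch not in "0123456789abcdefABCDEF" for ch in c[1:])
    ):
        raise ValueError(f"not a 6-digit hex color: {c!r}")
    return c


@dataclass(frozen=True)
class DisplayConfig:
    """Everything needed to resolve raw data into a display.

    missing_threshold is the fraction of window bins a run of empty bins must
    exceed (strictly) before the bridging line segment is drawn dashed.
    """

    window: tuple[datetime, datetime]
    goal: GoalRange = DEFAULT_GOAL
    systolic_color: str = SYSTOLIC_COLOR
    diastolic_color: str = DIASTOLIC_COLOR
    band_alpha: float = 0.18
    missing_threshold: float = 0.10
    smoothing: SmoothParams = field(default_factory=SmoothParams)

    def __post_init__(self) -> None:
        start, end = self.window
        if not start < end:
            raise ValueError("window start must precede end")
        _hex_color(self.systolic_color)
        _hex_color(self.diastolic_color)
        if not 0.0 < self.band_alpha <= 1.0:
            raise ValueError("band_alpha must be in (0, 1]")
        if not 0.0 < self.missing_threshold < 1.0:
            raise ValueError("missing_threshold must be in (0, 1)")

    @classmethod
    def for_days(cls, start: datetime, days: int, **kw) -> "DisplayConfig":
        return cls(window=(start, start + timedelta(days=days)), **kw)

    def with_(self, **kw) -> "DisplayConfig":
        return replace(self, **kw)
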