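"""Seeded generator of realistic home BP monitoring streams.

Every pipeline stage is testable without patient data: the generator
produces measurement series exhibiting the phenomena the display exists to
tame — circadian swing, autocorrelated day-to-day drift, white-coat offset
on office readings, occasional outliers, medication-response drops with an
onset delay, and runs of missing data.

The model is baseline + circadian sinusoid + AR(1) + white noise, with
additive office/outlier/medication terms.  It is the simplest process with
the right qualitative behavior, not a physiological claim.  Diastolic
deviations track systolic deviations at a factor of 0.62 plus independent
noise, so both channels stay mutually consistent (SBP > DBP) without a full
hemodynamic model.

All randomness derives from one integer seed via per-component substreams
(``default_rng([seed, k])``), so adding a feature never shifts the draws of
existing ones.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np

from .model import Annotation, BPMeasurement, MedicationCourse, Source

__all__ = ["MedEffect", "SimParams", "simulate_bp_series", "inject_missingness", "PRESETS", "preset_params"]

# substream indices (frozen; append only)
_SUB_AR = 0
_SUB_NOISE_S = 1
_SUB_NOISE_D = 2
_SUB_OUTLIER_MASK = 3
_SUB_OUTLIER_SIGN = 4

_DBP_COUPLING = 0.62
_DBP_NOISE_FACTOR = 0.6
_CIRCADIAN_PEAK_HOUR = 10.0  # morning surge


@dataclass(frozen=True)
class MedEffect:
    """A medication's response: a sigmoidal SBP drop of ``drop`` mmHg that
    begins ``onset_days`` after the course starts and ramps in over a few
    days (different drugs act on different timescales)."""

    course: MedicationCourse
    drop: float
    onset_days: float = 7.0
    ramp_days: float = 3.0

    def sbp_effect(self, t: datetime) -> float:
        t_days = (
            t - datetime.combine(self.course.start, datetime.min.time())
        ).total_seconds() / 86400.0
        if self.course.end is not None:
            end_days = (self.course.end - self.course.start).days
            if t_days > end_days:
                # effect washes out after the course ends, same ramp
                t_days = end_days - (t_days - end_days)
        z = (t_days - self.onset_days) / self.ramp_days
        return -self.drop / (1.0 + math.exp(-z))


@dataclass(frozen=True)
class SimParams:
    """Generator settings.  Defaults emulate a patient with managed stage-1
    hypertension on twice-daily home monitoring.

    baseline_sbp / baseline_dbp : mmHg, long-run means (135/85).
    circadian_amplitude : mmHg half-swing of the daily sinusoid (8).
    ar1_rho : lag-1 correlation of the slow AR(1) component (0.6).
    noise_sd : mmHg, both the AR(1) stationary SD and the white-noise SD (6).
    office_offset : mmHg added to office readings — white-coat effect (8).
    outlier_rate / outlier_shift : probability and size of spurious spikes.
    cadence : spacing between readings.
    office_every : every k-th reading is taken in the office (None = all home).
    """

    baseline_sbp: float = 135.0
    baseline_dbp: float = 85.0
    circadian_amplitude: float = 8.0
    ar1_rho: float = 0.6
    noise_sd: float = 6.0
    office_offset: float = 8.0
    outlier_rate: float = 0.01
    outlier_shift: float = 25.0
    cadence: timedelta = timedelta(hours=12)
    office_every: int | None = None
    missing_runs: tuple[tuple[datetime, timedelta], ...] = ()
    med_effects: tuple[MedEffect, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValueError("outlier_rate must be in [0, 1]")
        if not 0.0 <= self.ar1_rho < 1.0:
            raise ValueError("ar1_rho must be in [0, 1)")
        if self.cadence <= timedelta(0):
            raise ValueError("cadence must be positive")

    def with_(self, **kw) -> "SimParams":
        return replace(self, **kw)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def simulate_bp_series(
    params: SimParams, window: tuple[datetime, datetime]
) -> list[BPMeasurement]:
    """Generate one reading per cadence step across the window.

    Deterministic given ``params.seed``.  Values are clipped into the
    physiologic 30-300 mmHg bounds (with a warning) so every generated
    reading satisfies the measurement invariants.
    """
    start, end = window
    if not start < end:
        raise ValueError("window start must precede end")
    times: list[datetime] = []
    t = start
    while t < end:
        times.append(t)
        t += params.cadence
    n = len(times)
    if n == 0:
        return []

    rho = params.ar1_rho
    ar = np.zeros(n)
    ar_innov = _rng(params.seed, _SUB_AR).standard_normal(n)
    if params.noise_sd > 0:
        ar[0] = ar_innov[0] * params.noise_sd
        innov_sd = params.noise_sd * math.sqrt(1.0 - rho * rho)
        for i in range(1, n):
            ar[i] = rho * ar[i - 1] + innov_sd * ar_innov[i]

    eps_s = _rng(params.seed, _SUB_NOISE_S).standard_normal(n) * params.noise_sd
    eps_d = (
        _rng(params.seed, _SUB_NOISE_D).standard_normal(n)
        * params.noise_sd
        * _DBP_NOISE_FACTOR
    )
    out_mask = _rng(params.seed, _SUB_OUTLIER_MASK).random(n) < params.outlier_rate
    out_sign = _rng(params.seed, _SUB_OUTLIER_SIGN).choice([-1.0, 1.0], size=n)

    measurements = []
    clipped = 0
    for i, ti in enumerate(times):
        hours = ti.hour + ti.minute / 60.0
        circadian = params.circadian_amplitude * math.cos(
            2.0 * math.pi * (hours - _CIRCADIAN_PEAK_HOUR) / 24.0
        )
        is_office = (
            params.office_every is not None and i % params.office_every == 0
        )
        med = sum(e.sbp_effect(ti) for e in params.med_effects)
        dev = circadian + ar[i] + med  # shared systemic deviation
        sbp = (
            params.baseline_sbp
            + dev
            + eps_s[i]
            + (params.office_offset if is_office else 0.0)
            + (out_sign[i] * params.outlier_shift if out_mask[i] else 0.0)
        )
        dbp = params.baseline_dbp + _DBP_COUPLING * dev + eps_d[i]
        lo_s, hi_s = max(31.0, dbp + 1.0), 300.0
        if not lo_s <= sbp <= hi_s or not 30.0 <= dbp < sbp:
            clipped += 1
        dbp = min(max(dbp, 30.0), 298.0)
        sbp = min(max(sbp, dbp + 1.0), 300.0)
        measurements.append(
            BPMeasurement(
                timestamp=ti,
                systolic=float(sbp),
                diastolic=float(dbp),
                source=Source.OFFICE if is_office else Source.HOME,
                confirmed=not is_office,
            )
        )
    if clipped:
        warnings.warn(
            f"{clipped} generated readings clipped to physiologic bounds",
            stacklevel=2,
        )
    return measurements


def inject_missingness(
    series: list[BPMeasurement],
    runs: list[tuple[datetime, timedelta]],
) -> list[BPMeasurement]:
    """Remove every measurement inside each [start, start+length) run.

    Overlapping runs are merged (with a warning).  Emulates cuff vacations,
    dead batteries, and lapses between office visits.
    """
    if not runs:
        return list(series)
    intervals = sorted((s, s + d) for s, d in runs)
    merged = [intervals[0]]
    overlapped = False
    for a, b in intervals[1:]:
        if a < merged[-1][1]:
            overlapped = True
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    if overlapped:
        warnings.warn("overlapping missingness runs merged", stacklevel=2)
    return [
        m
        for m in series
        if not any(a <= m.timestamp < b for a, b in merged)
    ]


@dataclass(frozen=True)
class Preset:
    """A density-era scenario: measurement cadence and source pattern."""

    name: str
    description: str
    params: SimParams
    window_days: int


def preset_params(name: str, seed: int = 0) -> tuple[SimParams, int]:
    """Return (SimParams, window length in days) for a named scenario."""
    p = PRESETS[name]
    return p.params.with_(seed=seed), p.window_days


PRESETS: dict[str, Preset] = {
    # office-only era: quarterly visits over two years
    "dearth": Preset(
        name="dearth",
        description="office-only readings at roughly quarterly visits",
        params=SimParams(cadence=timedelta(days=91), office_every=1),
        window_days=731,
    ),
    # early home monitoring: weekly home readings, office visit ~quarterly
    "nascence": Preset(
        name="nascence",
        description="weekly home readings with occasional office visits",
        params=SimParams(cadence=timedelta(days=7), office_every=13),
        window_days=366,
    ),
    # wearable future: a reading every 10 minutes
    "abundance": Preset(
        name="abundance",
        description="passive monitoring at 10-minute cadence",
        params=SimParams(cadence=timedelta(minutes=10)),
        window_days=1,
    ),
}


def demo_medications(window_start: datetime) -> list[MedicationCourse]:
    """A small demo med list: a dose increase partway through the window."""
    d0 = window_start.date()
    return [
        MedicationCourse("Lisinopril", "10 mg daily", d0 + timedelta(days=10), d0 + timedelta(days=40)),
        MedicationCourse("Lisinopril", "20 mg daily", d0 + timedelta(days=40), None),
    ]


def demo_annotations(window_start: datetime) -> list[Annotation]:
    d0 = window_start.date()
    return [
        Annotation(d0 + timedelta(days=10), "Started lisinopril 10 mg"),
        Annotation(d0 + timedelta(days=25), "Began low-sodium diet"),
        Annotation(d0 + timedelta(days=40), "Dose increased to 20 mg"),
    ]
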