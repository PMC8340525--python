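"""Readers and writers: measurement CSV, FHIR R4 bundles, medication and
annotation CSVs, the display-model JSON document, and the rejects report.

Parsers never drop rows silently: every input row is either accepted or
recorded in a rejects report with the reason, so n_in = n_accepted +
n_rejected always holds.  Duplicate (timestamp, source) pairs — home cuffs
can re-transmit — collapse to the last occurrence, which is logged as a
reject with reason "duplicate".

CSV dialect is RFC 4180, UTF-8, ISO-8601 timestamps.  The FHIR reader
targets R4 Observation shapes only: a BP panel is LOINC 85354-9 with
components 8480-6 (systolic) and 8462-4 (diastolic).
"""

from __future__ import annotations

import csv
import io as _io
import json
import logging
from dataclasses import dataclass, field
from datetime import date, datetime

from .aggregate import (
    AggregatedPoint,
    BinSchedule,
    LineStyle,
    SegmentStyle,
)
from .display import (
    AnnotationMarker,
    DataTableRow,
    DisplayModel,
    MedicationLane,
)
from .model import (
    Annotation,
    AuthorRole,
    BPMeasurement,
    DisplayConfig,
    GoalRange,
    InvalidCourse,
    InvalidMeasurement,
    MedicationCourse,
    SmoothParams,
    Source,
    validate_measurement,
)
from .smooth import SmoothCurve

__all__ = [
    "ParseResult",
    "RejectedRow",
    "parse_bp_csv",
    "parse_bp_fhir_bundle",
    "parse_medications",
    "parse_annotations",
    "write_bp_csv",
    "write_rejects_csv",
    "write_points_csv",
    "write_display_json",
    "read_display_json",
    "MissingColumn",
    "EmptyFile",
    "NotABundle",
    "MalformedObservation",
    "UnparseableDate",
]

log = logging.getLogger(__name__)

LOINC_BP_PANEL = "85354-9"
LOINC_SYSTOLIC = "8480-6"
LOINC_DIASTOLIC = "8462-4"

# Source spellings accepted on input.  24-h ambulatory readings count as
# home for symbol purposes (flagged in ParseResult.warnings).
_SOURCE_ALIASES = {
    "home": Source.HOME,
    "office": Source.OFFICE,
    "clinic": Source.OFFICE,
    "inpatient": Source.INPATIENT,
    "hospital": Source.INPATIENT,
    "other": Source.OTHER,
    "ambulatory": Source.HOME,
    "24-h ambulatory": Source.HOME,
    "24h-ambulatory": Source.HOME,
}
_AMBULATORY = {"ambulatory", "24-h ambulatory", "24h-ambulatory"}


class MissingColumn(ValueError):
    pass


class EmptyFile(ValueError):
    pass


class NotABundle(ValueError):
    pass


class MalformedObservation(ValueError):
    pass


class UnparseableDate(ValueError):
    pass


@dataclass(frozen=True)
class RejectedRow:
    row: int  # 1-based data-row / entry number
    reason: str
    raw: str


@dataclass
class ParseResult:
    measurements: list[BPMeasurement] = field(default_factory=list)
    rejects: list[RejectedRow] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_input(self) -> int:
        return len(self.measurements) + len(self.rejects)


def _parse_source(raw: str, result: ParseResult, row: int) -> Source:
    key = (raw or "home").strip().lower()
    if key in _AMBULATORY:
        result.warnings.append(
            f"row {row}: 24-h ambulatory source mapped to home"
        )
    try:
        return _SOURCE_ALIASES[key]
    except KeyError:
        raise InvalidMeasurement(f"unknown source {raw!r}") from None


_TRUE = {"1", "true", "yes", "y", "t"}
_FALSE = {"0", "false", "no", "n", "f", ""}


def _parse_bool(raw: str) -> bool:
    key = (raw or "").strip().lower()
    if key in _TRUE:
        return True
    if key in _FALSE:
        return False
    raise InvalidMeasurement(f"unparseable boolean {raw!r}")


def _parse_ts(raw: str) -> datetime:
    try:
        return datetime.fromisoformat(raw.strip())
    except (ValueError, AttributeError) as exc:
        raise InvalidMeasurement(f"unparseable timestamp {raw!r}") from exc


def _dedupe_last_wins(
    result: ParseResult,
) -> None:
    seen: dict[tuple[datetime, Source], int] = {}
    keep = [True] * len(result.measurements)
    for i, m in enumerate(result.measurements):
        key = (m.timestamp, m.source)
        if key in seen:
            j = seen[key]
            keep[j] = False
            result.rejects.append(
                RejectedRow(
                    row=j + 1,
                    reason="duplicate (timestamp, source); last occurrence kept",
                    raw=f"{m.timestamp.isoformat()},{m.source.value}",
                )
            )
            log.info("duplicate reading at %s (%s): last wins", m.timestamp, m.source.value)
        seen[key] = i
    result.measurements = [m for m, k in zip(result.measurements, keep) if k]


def parse_bp_csv(
    stream: str | _io.TextIOBase,
    column_map: dict[str, str] | None = None,
) -> ParseResult:
    """Parse a measurement CSV into validated readings plus a rejects report.

    Required columns: timestamp, systolic, diastolic, source ("confirmed"
    optional, defaults false).  ``column_map`` renames logical to actual
    column names.  Output is sorted ascending by timestamp; duplicate
    (timestamp, source) pairs keep the last occurrence.
    """
    if isinstance(stream, str):
        stream = _io.StringIO(stream)
    cmap = {
        k: (column_map or {}).get(k, k)
        for k in ("timestamp", "systolic", "diastolic", "source", "confirmed")
    }
    reader = csv.DictReader(stream)
    if reader.fieldnames is None:
        raise EmptyFile("no header row")
    for col in ("timestamp", "systolic", "diastolic", "source"):
        if cmap[col] not in reader.fieldnames:
            raise MissingColumn(f"missing column {cmap[col]!r}")
    has_confirmed = cmap["confirmed"] in reader.fieldnames

    result = ParseResult()
    for i, row in enumerate(reader, start=1):
        raw = ",".join("" if v is None else str(v) for v in row.values())
        try:
            m = BPMeasurement(
                timestamp=_parse_ts(row[cmap["timestamp"]]),
                systolic=float(row[cmap["systolic"]]),
                diastolic=float(row[cmap["diastolic"]]),
                source=_parse_source(row[cmap["source"]], result, i),
                confirmed=_parse_bool(row[cmap["confirmed"]]) if has_confirmed else False,
            )
            result.measurements.append(validate_measurement(m))
        except (InvalidMeasurement, TypeError, ValueError) as exc:
            result.rejects.append(RejectedRow(row=i, reason=str(exc), raw=raw))
    result.measurements.sort(key=lambda m: m.timestamp)
    _dedupe_last_wins(result)
    return result


def _codes(codeable: dict | None) -> set[str]:
    return {
        c.get("code")
        for c in (codeable or {}).get("coding", [])
        if c.get("code")
    }


def _fhir_source(obs: dict, result: ParseResult, idx: int) -> Source:
    # Documented mapping order: a measurement-setting extension wins, then
    # any category coding whose code/display names a known source, else
    # office (clinic-recorded resources are the default FHIR producer).
    for ext in obs.get("extension", []):
        if str(ext.get("url", "")).endswith("measurement-setting"):
            val = ext.get("valueCode") or ext.get("valueString") or ""
            if val.strip().lower() in _SOURCE_ALIASES:
                return _parse_source(val, result, idx)
    for cat in obs.get("category", []):
        for coding in cat.get("coding", []):
            for candidate in (coding.get("code"), coding.get("display")):
                if candidate and candidate.strip().lower() in _SOURCE_ALIASES:
                    return _parse_source(candidate, result, idx)
    return Source.OFFICE


def _fhir_confirmed(obs: dict) -> bool:
    # No standard FHIR field records staff validation of a home cuff; we
    # accept a boolean extension ending in "home-confirmed", else False.
    for ext in obs.get("extension", []):
        if str(ext.get("url", "")).endswith("home-confirmed"):
            return bool(ext.get("valueBoolean", False))
    return False


def parse_bp_fhir_bundle(text: str) -> ParseResult:
    """Extract BP readings from a FHIR R4 Bundle of Observation resources.

    One reading per complete BP panel (LOINC 85354-9 with both the systolic
    and diastolic components); incomplete panels are rejected, non-BP
    Observations ignored.
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise NotABundle(f"not JSON: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("resourceType") != "Bundle":
        raise NotABundle("resourceType is not 'Bundle'")

    result = ParseResult()
    panel_idx = 0
    for entry in doc.get("entry", []):
        obs = entry.get("resource", {}) if isinstance(entry, dict) else {}
        if obs.get("resourceType") != "Observation":
            continue
        if LOINC_BP_PANEL not in _codes(obs.get("code")):
            continue
        panel_idx += 1
        try:
            comps = {}
            for comp in obs.get("component", []):
                codes = _codes(comp.get("code"))
                value = comp.get("valueQuantity", {}).get("value")
                if LOINC_SYSTOLIC in codes:
                    comps["systolic"] = value
                elif LOINC_DIASTOLIC in codes:
                    comps["diastolic"] = value
            if comps.get("systolic") is None or comps.get("diastolic") is None:
                raise MalformedObservation(
                    "incomplete panel: missing systolic or diastolic component"
                )
            when = obs.get("effectiveDateTime")
            if not when:
                raise MalformedObservation("missing effectiveDateTime")
            m = BPMeasurement(
                timestamp=_parse_ts(when),
                systolic=float(comps["systolic"]),
                diastolic=float(comps["diastolic"]),
                source=_fhir_source(obs, result, panel_idx),
                confirmed=_fhir_confirmed(obs),
            )
            result.measurements.append(validate_measurement(m))
        except (MalformedObservation, InvalidMeasurement, TypeError, ValueError) as exc:
            result.rejects.append(
                RejectedRow(
                    row=panel_idx,
                    reason=str(exc),
                    raw=obs.get("id", f"entry-{panel_idx}"),
                )
            )
    result.measurements.sort(key=lambda m: m.timestamp)
    _dedupe_last_wins(result)
    return result


def _parse_date(raw: str, what: str) -> date:
    try:
        return date.fromisoformat(raw.strip())
    except (ValueError, AttributeError) as exc:
        raise UnparseableDate(f"unparseable {what} date {raw!r}") from exc


def parse_medications(stream: str | _io.TextIOBase) -> list[MedicationCourse]:
    """Parse a medication CSV (name, dose, start, end; blank end = ongoing).

    Courses are returned sorted by (name, start).  Overlapping same-name
    courses are allowed: a dose change is two adjacent courses in one lane.
    """
    if isinstance(stream, str):
        stream = _io.StringIO(stream)
    reader = csv.DictReader(stream)
    if reader.fieldnames is None:
        return []
    for col in ("name", "dose", "start", "end"):
        if col not in reader.fieldnames:
            raise MissingColumn(f"missing column {col!r}")
    courses = []
    for row in reader:
        end_raw = (row["end"] or "").strip()
        courses.append(
            MedicationCourse(
                name=row["name"].strip(),
                dose=row["dose"].strip(),
                start=_parse_date(row["start"], "start"),
                end=_parse_date(end_raw, "end") if end_raw else None,
            )
        )
    return sorted(courses, key=lambda c: (c.name, c.start))


def parse_annotations(stream: str | _io.TextIOBase) -> list[Annotation]:
    """Parse an annotation CSV (date, text; author_role optional)."""
    if isinstance(stream, str):
        stream = _io.StringIO(stream)
    reader = csv.DictReader(stream)
    if reader.fieldnames is None:
        return []
    for col in ("date", "text"):
        if col not in reader.fieldnames:
            raise MissingColumn(f"missing column {col!r}")
    out = []
    for row in reader:
        role = (row.get("author_role") or "patient").strip().lower()
        out.append(
            Annotation(
                date=_parse_date(row["date"], "annotation"),
                text=row["text"],
                author_role=AuthorRole(role),
            )
        )
    return sorted(out, key=lambda a: a.date)


def write_bp_csv(measurements: list[BPMeasurement]) -> str:
    buf = _io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["timestamp", "systolic", "diastolic", "source", "confirmed"])
    for m in measurements:
        w.writerow(
            [
                m.timestamp.isoformat(),
                repr(float(m.systolic)),
                repr(float(m.diastolic)),
                m.source.value,
                str(m.confirmed).lower(),
            ]
        )
    return buf.getvalue()


def write_rejects_csv(rejects: list[RejectedRow]) -> str:
    buf = _io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["row", "reason", "raw"])
    for r in rejects:
        w.writerow([r.row, r.reason, r.raw])
    return buf.getvalue()


def write_points_csv(points: list[AggregatedPoint]) -> str:
    buf = _io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(
        [
            "bin_index",
            "bin_start",
            "bin_end",
            "mean_systolic",
            "mean_diastolic",
            "n_measurements",
            "source_symbol",
        ]
    )
    for p in points:
        w.writerow(
            [
                p.bin_index,
                p.bin_interval[0].isoformat(),
                p.bin_interval[1].isoformat(),
                f"{p.mean_systolic:.6g}",
                f"{p.mean_diastolic:.6g}",
                p.n_measurements,
                p.source_symbol,
            ]
        )
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Display-model JSON: a loss-free, diff-stable document (sorted keys).

def _iso(dt: datetime) -> str:
    return dt.isoformat()


def _curve_dict(c: SmoothCurve | None) -> dict | None:
    if c is None:
        return None
    return {"x": [float(v) for v in c.x], "fitted": [float(v) for v in c.fitted]}


def write_display_json(model: DisplayModel) -> str:
    """Serialize a DisplayModel; read_display_json(write_display_json(m))
    reproduces every panel's contents."""
    doc = {
        "window": [_iso(model.window[0]), _iso(model.window[1])],
        "schedule": {
            "window_label": model.schedule.window_label,
            "max_window_days": model.schedule.max_window_days,
            "bin_width": {
                "amount": model.schedule.bin_width.amount,
                "unit": model.schedule.bin_width.unit,
            },
            "max_points": model.schedule.max_points,
        },
        "bins": [[_iso(a), _iso(b)] for a, b in model.bins],
        "points": [
            {
                "bin_index": p.bin_index,
                "bin_interval": [_iso(p.bin_interval[0]), _iso(p.bin_interval[1])],
                "mean_systolic": p.mean_systolic,
                "mean_diastolic": p.mean_diastolic,
                "n_measurements": p.n_measurements,
                "source_symbol": p.source_symbol,
            }
            for p in model.points
        ],
        "segments": [
            {"span": list(s.span), "style": s.style.value} for s in model.segments
        ],
        "smooth_systolic": _curve_dict(model.smooth_systolic),
        "smooth_diastolic": _curve_dict(model.smooth_diastolic),
        "table": [
            {
                "label": r.label,
                "systolic_text": r.systolic_text,
                "diastolic_text": r.diastolic_text,
                "bold_systolic": r.bold_systolic,
                "bold_diastolic": r.bold_diastolic,
                "gap": r.gap,
            }
            for r in model.table
        ],
        "annotations": [
            {"date": a.date.isoformat(), "texts": list(a.texts)}
            for a in model.annotations
        ],
        "med_lanes": [
            {
                "name": lane.name,
                "intervals": [
                    [a.isoformat(), b.isoformat(), dose]
                    for a, b, dose in lane.intervals
                ],
            }
            for lane in model.med_lanes
        ],
        "goal": {
            "sbp_low": model.goal.sbp_low,
            "sbp_high": model.goal.sbp_high,
            "dbp_low": model.goal.dbp_low,
            "dbp_high": model.goal.dbp_high,
        },
        "config": {
            "systolic_color": model.config.systolic_color,
            "diastolic_color": model.config.diastolic_color,
            "band_alpha": model.config.band_alpha,
            "missing_threshold": model.config.missing_threshold,
            "smoothing": {
                "frac": model.config.smoothing.frac,
                "robust_iterations": model.config.smoothing.robust_iterations,
                "enabled": model.config.smoothing.enabled,
            },
        },
        "y_domain": list(model.y_domain),
    }
    return json.dumps(doc, indent=2, sort_keys=True)


def read_display_json(text: str) -> DisplayModel:
    """Inverse of write_display_json."""
    import numpy as np

    from .aggregate import BinWidth

    doc = json.loads(text)
    window = (
        datetime.fromisoformat(doc["window"][0]),
        datetime.fromisoformat(doc["window"][1]),
    )
    sched = doc["schedule"]
    schedule = BinSchedule(
        window_label=sched["window_label"],
        max_window_days=sched["max_window_days"],
        bin_width=BinWidth(sched["bin_width"]["amount"], sched["bin_width"]["unit"]),
        max_points=sched["max_points"],
    )
    goal = GoalRange(**doc["goal"])
    cfg = doc["config"]
    config = DisplayConfig(
        window=window,
        goal=goal,
        systolic_color=cfg["systolic_color"],
        diastolic_color=cfg["diastolic_color"],
        band_alpha=cfg["band_alpha"],
        missing_threshold=cfg["missing_threshold"],
        smoothing=SmoothParams(**cfg["smoothing"]),
    )

    def curve(d: dict | None) -> SmoothCurve | None:
        if d is None:
            return None
        return SmoothCurve(x=np.array(d["x"]), fitted=np.array(d["fitted"]))

    return DisplayModel(
        window=window,
        schedule=schedule,
        bins=[
            (datetime.fromisoformat(a), datetime.fromisoformat(b))
            for a, b in doc["bins"]
        ],
        points=[
            AggregatedPoint(
                bin_index=p["bin_index"],
                bin_interval=(
                    datetime.fromisoformat(p["bin_interval"][0]),
                    datetime.fromisoformat(p["bin_interval"][1]),
                ),
                mean_systolic=p["mean_systolic"],
                mean_diastolic=p["mean_diastolic"],
                n_measurements=p["n_measurements"],
                source_symbol=p["source_symbol"],
            )
            for p in doc["points"]
        ],
        segments=[
            SegmentStyle(span=tuple(s["span"]), style=LineStyle(s["style"]))
            for s in doc["segments"]
        ],
        smooth_systolic=curve(doc["smooth_systolic"]),
        smooth_diastolic=curve(doc["smooth_diastolic"]),
        table=[DataTableRow(**r) for r in doc["table"]],
        annotations=[
            AnnotationMarker(
                date=date.fromisoformat(a["date"]), texts=tuple(a["texts"])
            )
            for a in doc["annotations"]
        ],
        med_lanes=[
            MedicationLane(
                name=lane["name"],
                intervals=tuple(
                    (date.fromisoformat(a), date.fromisoformat(b), dose)
                    for a, b, dose in lane["intervals"]
                ),
            )
            for lane in doc["med_lanes"]
        ],
        goal=goal,
        config=config,
        y_domain=tuple(doc["y_domain"]),
    )
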