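"""Deterministic rendering of a DisplayModel to SVG and self-contained HTML.

All panels — BP plot, annotation track, data table, medication timeline —
stack vertically and share a single x (time) scale, declared once per panel
as data attributes so interactive code (and tests) can assert that any pixel
maps to the same date in every panel.  The HTML output adds a cursor-tracking
vertical scrubber bar spanning all panels and hover-revealed annotation
bubbles; the static SVG substitutes a numbered footnote list so printing
loses no information.

Output is byte-deterministic: no timestamps, fixed 3-decimal float
formatting, stable element order.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from xml.sax.saxutils import escape

from .aggregate import LineStyle
from .display import DisplayModel, round_half_up
from .model import DIASTOLIC_COLOR, SYSTOLIC_COLOR

__all__ = ["RenderTheme", "render_svg", "render_html"]


@dataclass(frozen=True)
class RenderTheme:
    """Visual constants.

    Goal bands use each channel's hue at low alpha ("pastel"); the raw line
    is faded so the smoothing line stands out.
    """

    systolic_color: str = SYSTOLIC_COLOR
    diastolic_color: str = DIASTOLIC_COLOR
    band_alpha: float = 0.18
    raw_opacity: float = 0.45
    smooth_opacity: float = 1.0
    raw_width: float = 1.2
    smooth_width: float = 2.5
    marker_radius: float = 3.0
    dash_pattern: str = "6,5"
    width: int = 960
    plot_height: int = 280
    margin_left: int = 60
    margin_right: int = 20

    def __post_init__(self) -> None:
        if not self.raw_opacity < self.smooth_opacity:
            raise ValueError("raw line must be fainter than the smooth line")

    @classmethod
    def from_config(cls, config) -> "RenderTheme":
        return cls(
            systolic_color=config.systolic_color,
            diastolic_color=config.diastolic_color,
            band_alpha=config.band_alpha,
        )


def _f(v: float) -> str:
    return f"{v:.3f}"


class _XScale:
    def __init__(self, model: DisplayModel, theme: RenderTheme) -> None:
        self.t0, self.t1 = model.window
        self.x0 = float(theme.margin_left)
        self.x1 = float(theme.width - theme.margin_right)
        self._span = (self.t1 - self.t0).total_seconds()

    def __call__(self, t: datetime) -> float:
        frac = (t - self.t0).total_seconds() / self._span
        return self.x0 + frac * (self.x1 - self.x0)

    def attrs(self) -> str:
        return (
            f'data-t0="{self.t0.isoformat()}" data-t1="{self.t1.isoformat()}" '
            f'data-x0="{_f(self.x0)}" data-x1="{_f(self.x1)}"'
        )


class _YScale:
    def __init__(self, domain: tuple[float, float], top: float, bottom: float):
        self.lo, self.hi = domain
        self.top, self.bottom = top, bottom

    def __call__(self, v: float) -> float:
        frac = (v - self.lo) / (self.hi - self.lo)
        return self.bottom - frac * (self.bottom - self.top)


def _x_ticks(model: DisplayModel) -> list[datetime]:
    bounds = [b[0] for b in model.bins] + [model.bins[-1][1]]
    step = max(1, (len(bounds) - 1) // 8)
    return bounds[::step]


def _tick_label(t: datetime, bin_width) -> str:
    if not bin_width.is_calendar and bin_width.as_timedelta() < timedelta(days=1):
        return t.strftime("%H:%M")
    return t.strftime("%Y-%m-%d")


def _plot_panel(model: DisplayModel, theme: RenderTheme, xs: _XScale, top: float) -> tuple[list[str], float]:
    bottom = top + theme.plot_height
    ys = _YScale(model.y_domain, top + 10, bottom - 10)
    g = model.goal
    out = [f'<g class="panel panel-plot" {xs.attrs()}>']

    # goal-range bands, behind everything (like-with-like hues)
    for low, high, color, name in (
        (g.sbp_low, g.sbp_high, theme.systolic_color, "systolic"),
        (g.dbp_low, g.dbp_high, theme.diastolic_color, "diastolic"),
    ):
        out.append(
            f'<rect class="band band-{name}" x="{_f(xs.x0)}" y="{_f(ys(high))}" '
            f'width="{_f(xs.x1 - xs.x0)}" height="{_f(ys(low) - ys(high))}" '
            f'fill="{color}" fill-opacity="{_f(theme.band_alpha)}"/>'
        )

    # y axis: ticks every 20 mmHg
    out.append(
        f'<line x1="{_f(xs.x0)}" y1="{_f(top + 10)}" x2="{_f(xs.x0)}" '
        f'y2="{_f(bottom - 10)}" stroke="#444" stroke-width="1"/>'
    )
    v = 20.0 * round_half_up(ys.lo / 20.0)
    while v <= ys.hi:
        if v >= ys.lo:
            out.append(
                f'<line x1="{_f(xs.x0 - 4)}" y1="{_f(ys(v))}" x2="{_f(xs.x0)}" '
                f'y2="{_f(ys(v))}" stroke="#444" stroke-width="1"/>'
                f'<text x="{_f(xs.x0 - 8)}" y="{_f(ys(v) + 3)}" '
                f'font-size="9" text-anchor="end" fill="#444">{round_half_up(v)}</text>'
            )
        v += 20.0
    out.append(
        f'<text x="12" y="{_f((top + bottom) / 2)}" font-size="10" fill="#444" '
        f'transform="rotate(-90 12 {_f((top + bottom) / 2)})" '
        f'text-anchor="middle">mmHg</text>'
    )

    # x axis line + ticks
    out.append(
        f'<line class="x-axis" x1="{_f(xs.x0)}" y1="{_f(bottom)}" '
        f'x2="{_f(xs.x1)}" y2="{_f(bottom)}" stroke="#444" stroke-width="1"/>'
    )
    for t in _x_ticks(model):
        out.append(
            f'<line x1="{_f(xs(t))}" y1="{_f(bottom)}" x2="{_f(xs(t))}" '
            f'y2="{_f(bottom + 4)}" stroke="#444" stroke-width="1"/>'
            f'<text x="{_f(xs(t))}" y="{_f(bottom + 15)}" font-size="8" '
            f'text-anchor="middle" fill="#444">'
            f"{_tick_label(t, model.schedule.bin_width)}</text>"
        )

    by_index = {p.bin_index: p for p in model.points}
    raw_opacity = theme.raw_opacity if model.smooth_systolic is not None else 1.0

    # connecting segments, per channel, dashed over large missing runs
    for seg in model.segments:
        a, b = by_index[seg.span[0]], by_index[seg.span[1]]
        dash = (
            f' stroke-dasharray="{theme.dash_pattern}"'
            if seg.style is LineStyle.DASHED
            else ""
        )
        for attr, color, name in (
            ("mean_systolic", theme.systolic_color, "systolic"),
            ("mean_diastolic", theme.diastolic_color, "diastolic"),
        ):
            out.append(
                f'<line class="segment segment-{name} segment-{seg.style.value}" '
                f'x1="{_f(xs(a.time))}" y1="{_f(ys(getattr(a, attr)))}" '
                f'x2="{_f(xs(b.time))}" y2="{_f(ys(getattr(b, attr)))}" '
                f'stroke="{color}" stroke-width="{_f(theme.raw_width)}" '
                f'stroke-opacity="{_f(raw_opacity)}"{dash}/>'
            )

    # markers: circles for home, squares for office/clinical
    r = theme.marker_radius
    for p in model.points:
        for v, color, name in (
            (p.mean_systolic, theme.systolic_color, "systolic"),
            (p.mean_diastolic, theme.diastolic_color, "diastolic"),
        ):
            cx, cy = xs(p.time), ys(v)
            if p.source_symbol == "circle_home":
                out.append(
                    f'<circle class="marker marker-{name} marker-home" '
                    f'cx="{_f(cx)}" cy="{_f(cy)}" r="{_f(r)}" fill="{color}" '
                    f'fill-opacity="{_f(raw_opacity)}"/>'
                )
            else:
                out.append(
                    f'<rect class="marker marker-{name} marker-office" '
                    f'x="{_f(cx - r)}" y="{_f(cy - r)}" width="{_f(2 * r)}" '
                    f'height="{_f(2 * r)}" fill="{color}" '
                    f'fill-opacity="{_f(raw_opacity)}"/>'
                )

    # LOWESS trend, full opacity and heavier stroke
    for curve, color, name in (
        (model.smooth_systolic, theme.systolic_color, "systolic"),
        (model.smooth_diastolic, theme.diastolic_color, "diastolic"),
    ):
        if curve is None:
            continue
        pts = " ".join(
            f"{_f(xs(model.window[0] + timedelta(days=float(xv))))},{_f(ys(float(fv)))}"
            for xv, fv in zip(curve.x, curve.fitted)
        )
        out.append(
            f'<polyline class="smooth smooth-{name}" points="{pts}" '
            f'fill="none" stroke="{color}" stroke-width="{_f(theme.smooth_width)}" '
            f'stroke-opacity="{_f(theme.smooth_opacity)}"/>'
        )
    out.append("</g>")
    return out, bottom + 20  # room for tick labels


def _annotation_panel(
    model: DisplayModel,
    theme: RenderTheme,
    xs: _XScale,
    top: float,
    interactive: bool,
) -> tuple[list[str], float]:
    h = 22.0
    out = [f'<g class="panel panel-annotations" {xs.attrs()}>']
    for i, marker in enumerate(model.annotations, start=1):
        x = xs(datetime.combine(marker.date, datetime.min.time()))
        cy = top + 8
        out.append(f'<g class="annotation">')
        out.append(
            f'<path class="annotation-marker" d="M {_f(x)} {_f(cy - 5)} '
            f"L {_f(x + 5)} {_f(cy)} L {_f(x)} {_f(cy + 5)} "
            f'L {_f(x - 5)} {_f(cy)} Z" fill="#666"/>'
        )
        out.append(
            f'<text x="{_f(x)}" y="{_f(cy + 2.5)}" font-size="6" fill="#fff" '
            f'text-anchor="middle">{i}</text>'
        )
        if interactive:
            text = escape(" | ".join(marker.texts))
            bw = 6.0 * len(text) + 10
            bx = min(max(x - bw / 2, xs.x0), xs.x1 - bw)
            out.append(
                f'<g class="annotation-bubble" visibility="hidden">'
                f'<rect x="{_f(bx)}" y="{_f(cy + 7)}" width="{_f(bw)}" height="16" '
                f'rx="4" fill="#333" fill-opacity="0.9"/>'
                f'<text x="{_f(bx + bw / 2)}" y="{_f(cy + 18)}" font-size="9" '
                f'fill="#fff" text-anchor="middle">{text}</text>'
                f"</g>"
            )
        out.append("</g>")
    out.append("</g>")
    return out, top + h + (18.0 if interactive and model.annotations else 0.0)


def _table_panel(model: DisplayModel, theme: RenderTheme, xs: _XScale, top: float) -> tuple[list[str], float]:
    row_h = 16.0
    out = [f'<g class="panel panel-table" {xs.attrs()}>']
    n = len(model.bins)
    cell_w = (xs.x1 - xs.x0) / max(n, 1)
    font = min(9.0, max(5.0, cell_w * 0.45))
    for j, (label, color, key_text, key_bold) in enumerate(
        (
            ("SBP", theme.systolic_color, "systolic_text", "bold_systolic"),
            ("DBP", theme.diastolic_color, "diastolic_text", "bold_diastolic"),
        )
    ):
        y = top + (j + 1) * row_h - 4
        out.append(
            f'<text x="{_f(xs.x0 - 8)}" y="{_f(y)}" font-size="9" '
            f'text-anchor="end" fill="{color}">{label}</text>'
        )
        for i, row in enumerate(model.table):
            cx = xs.x0 + (i + 0.5) * cell_w
            bold = ' font-weight="bold"' if getattr(row, key_bold) else ""
            cls = "cell cell-gap" if row.gap else "cell"
            out.append(
                f'<text class="{cls}" x="{_f(cx)}" y="{_f(y)}" '
                f'font-size="{_f(font)}" text-anchor="middle" '
                f'fill="#333"{bold}>{escape(getattr(row, key_text))}</text>'
            )
    out.append(
        f'<line x1="{_f(xs.x0)}" y1="{_f(top + 2 * row_h + 2)}" '
        f'x2="{_f(xs.x1)}" y2="{_f(top + 2 * row_h + 2)}" '
        f'stroke="#ccc" stroke-width="0.5"/>'
    )
    out.append("</g>")
    return out, top + 2 * row_h + 10


def _med_panel(model: DisplayModel, theme: RenderTheme, xs: _XScale, top: float) -> tuple[list[str], float]:
    lane_h = 18.0
    out = [f'<g class="panel panel-medications" {xs.attrs()}>']
    for j, lane in enumerate(model.med_lanes):
        y = top + j * lane_h
        out.append(
            f'<text x="{_f(xs.x0 - 8)}" y="{_f(y + 12)}" font-size="9" '
            f'text-anchor="end" fill="#333">{escape(lane.name)}</text>'
        )
        for a, b, dose in lane.intervals:
            x0 = xs(datetime.combine(a, datetime.min.time()))
            x1 = xs(datetime.combine(b, datetime.min.time()))
            out.append(
                f'<rect class="med-bar" x="{_f(x0)}" y="{_f(y + 3)}" '
                f'width="{_f(max(x1 - x0, 1.0))}" height="12" rx="3" '
                f'fill="#888" fill-opacity="0.6"/>'
                f'<text x="{_f((x0 + x1) / 2)}" y="{_f(y + 12)}" font-size="8" '
                f'text-anchor="middle" fill="#000">{escape(dose)}</text>'
            )
    out.append("</g>")
    return out, top + max(len(model.med_lanes), 1) * lane_h + 6


def _footnotes(model: DisplayModel, xs: _XScale, top: float) -> tuple[list[str], float]:
    if not model.annotations:
        return [], top
    out = [f'<g class="panel panel-footnotes">']
    y = top + 12
    out.append(
        f'<text x="{_f(xs.x0)}" y="{_f(y)}" font-size="9" fill="#333" '
        f'font-weight="bold">Annotations</text>'
    )
    for i, marker in enumerate(model.annotations, start=1):
        y += 13
        text = escape("; ".join(marker.texts))
        out.append(
            f'<text x="{_f(xs.x0)}" y="{_f(y)}" font-size="9" fill="#333">'
            f"{i}. {marker.date.isoformat()}: {text}</text>"
        )
    out.append("</g>")
    return out, y + 8


def _render_body(
    model: DisplayModel, theme: RenderTheme, interactive: bool
) -> tuple[str, float, _XScale]:
    xs = _XScale(model, theme)
    parts: list[str] = []
    top = 8.0
    for panel in (
        lambda t: _plot_panel(model, theme, xs, t),
        lambda t: _annotation_panel(model, theme, xs, t, interactive),
        lambda t: _table_panel(model, theme, xs, t),
        lambda t: _med_panel(model, theme, xs, t),
    ):
        chunk, top = panel(top)
        parts.extend(chunk)
    if not interactive:
        chunk, top = _footnotes(model, xs, top)
        parts.extend(chunk)
    if interactive:
        parts.append(
            f'<line id="scrubber" x1="{_f(xs.x0)}" y1="8" x2="{_f(xs.x0)}" '
            f'y2="{_f(top)}" stroke="#d33" stroke-width="1.5" visibility="hidden"/>'
            f'<text id="scrubber-label" x="{_f(xs.x0)}" y="{_f(top + 12)}" '
            f'font-size="10" fill="#d33" text-anchor="middle"></text>'
        )
        top += 18
    return "\n".join(parts), top + 8, xs


def render_svg(model: DisplayModel, theme: RenderTheme | None = None) -> str:
    """Render to static, print-safe SVG.

    Identical models render to byte-identical documents.  Annotation texts
    appear as a numbered footnote list since hover is unavailable in print.
    """
    theme = theme or RenderTheme.from_config(model.config)
    body, height, _ = _render_body(model, theme, interactive=False)
    return (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{theme.width}" '
        f'height="{round_half_up(height)}" viewBox="0 0 {theme.width} '
        f'{round_half_up(height)}" font-family="sans-serif">\n'
        f"{body}\n</svg>\n"
    )


_SCRUBBER_JS = """
(function () {
  var svg = document.getElementById('bpviz');
  var line = document.getElementById('scrubber');
  var label = document.getElementById('scrubber-label');
  var panel = svg.querySelector('.panel');
  var x0 = parseFloat(panel.getAttribute('data-x0'));
  var x1 = parseFloat(panel.getAttribute('data-x1'));
  var t0 = new Date(panel.getAttribute('data-t0')).getTime();
  var t1 = new Date(panel.getAttribute('data-t1')).getTime();
  svg.addEventListener('mousemove', function (evt) {
    var pt = svg.createSVGPoint();
    pt.x = evt.clientX; pt.y = evt.clientY;
    var p = pt.matrixTransform(svg.getScreenCTM().inverse());
    var x = Math.min(Math.max(p.x, x0), x1);
    line.setAttribute('x1', x); line.setAttribute('x2', x);
    line.setAttribute('visibility', 'visible');
    var t = new Date(t0 + (x - x0) / (x1 - x0) * (t1 - t0));
    label.setAttribute('x', x);
    label.textContent = t.toISOString().slice(0, 10);
  });
  svg.addEventListener('mouseleave', function () {
    line.setAttribute('visibility', 'hidden');
    label.textContent = '';
  });
})();
"""

_HOVER_CSS = """
.annotation:hover .annotation-bubble { visibility: visible; }
body { margin: 16px; font-family: sans-serif; background: #fff; }
"""


def render_html(model: DisplayModel, theme: RenderTheme | None = None) -> str:
    """Render to a self-contained interactive HTML file (no network access
    needed): hover-revealed annotation bubbles and a vertical scrubber bar
    that tracks the cursor across every panel on the shared x-scale."""
    theme = theme or RenderTheme.from_config(model.config)
    body, height, _ = _render_body(model, theme, interactive=True)
    return (
        "<!DOCTYPE html>\n"
        '<html lang="en"><head><meta charset="utf-8"/>'
        "<title>Blood pressure display</title>"
        f"<style>{_HOVER_CSS}</style></head>\n<body>\n"
        f'<svg id="bpviz" xmlns="http://www.w3.org/2000/svg" '
        f'width="{theme.width}" height="{round_half_up(height)}" '
        f'viewBox="0 0 {theme.width} {round_half_up(height)}" '
        f'font-family="sans-serif">\n{body}\n</svg>\n'
        f"<script>{_SCRUBBER_JS}</script>\n</body></html>\n"
    )
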