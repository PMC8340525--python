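# bpviz

Home blood-pressure monitors are turning BP records from a handful of office
readings per year into a stream of thousands of home measurements — data with
more predictive value than clinic readings, but which patients and clinicians
struggle to read off current EHR charts: axes autoscaled away from meaningful
baselines, no goal ranges, outliers dominating attention, and medications on
a different screen from the pressures they explain.

`bpviz` is a display engine for this data, built for shared decision making
around hypertension management. It ingests BP measurement series (CSV or FHIR
R4 Observation bundles), medication course lists, and free-text annotations,
and resolves them into a linked multi-panel display rendered as static SVG or
self-contained interactive HTML:

- **BP plot** — a two-line graph (systolic and diastolic), home readings as
  circles and office readings as squares, over **goal-range bands** drawn in
  each channel's hue (mint `#008471` for systolic, cocoa `#9C652B` for
  diastolic; defaults 90–140 / 60–90 mmHg, personalizable). The
  *like-with-like* paradigm makes control legible at a glance: a point is in
  range iff it sits inside the band of its own color. Out-of-range values get
  no extra plot affordance — the band alone carries the message.
- **Density-scheduled aggregation** — any requested window maps to a bin
  width that caps the display at ≤ 62 points (30-minute bins for a 1-day
  view, daily bins for 2 months, weekly bins for a year, …). Each point is
  the arithmetic mean of its bin's readings; a count-weighted mean of the
  plotted points always equals the raw grand mean.
- **LOWESS trend** — robust locally weighted regression (tricube kernel,
  bisquare robustness passes, time-based neighborhoods that span gaps)
  overlaid at full opacity on the slightly faded raw line, so the clinically
  meaningful mean trend dominates the visual weight of outliers.
- **Missing data** — empty bins leave gaps in the data table; a run of empty
  bins longer than 10% of the window's bins is bridged with a dashed line
  segment, shorter runs solid, so the amount of missing data is readable from
  the line style.
- **Data table** — one column per bin, aligned under the plot; values are
  bold when out of range *or* when the point aggregates more than one reading
  (dual encoding).
- **Annotation timeline** — dated notes as markers on the shared x-axis,
  hover-revealed in HTML, listed as numbered footnotes in print SVG.
- **Medication timeline** — one lane per drug, dose changes as adjacent
  intervals, so BP response can be read against treatment changes.
- **Scrubber bar** (HTML) — a vertical cursor-tracking line spanning every
  panel; all panels declare one identical x-scale.

A seeded synthetic generator (`bpviz.synthetic`) emulates home-monitoring
streams — circadian swing, AR(1) drift, white-coat office offset, outliers,
medication-response drops with onset delay, missing-data runs — so the whole
pipeline is testable and demo-able without patient data.

## Worked example

```
$ bpviz simulate --preset nascence --seed 7 --start 2021-01-01T00:00 --out-dir demo
wrote 53 measurements, 2 courses, 3 annotations to demo

$ bpviz aggregate --in demo/measurements.csv --start 2021-01-01T00:00 --window 62 --out demo/points.csv
2 months schedule: 62 bins of 1 day, 9 points, 0 rejected rows

$ head -3 demo/points.csv
bin_index,bin_start,bin_end,mean_systolic,mean_diastolic,n_measurements,source_symbol
0,2021-01-01T00:00:00,2021-01-02T00:00:00,138.163,81.3395,1,square_office
7,2021-01-08T00:00:00,2021-01-09T00:00:00,115.483,79.7578,1,circle_home

$ bpviz render --in demo/measurements.csv --meds demo/medications.csv \
    --annotations demo/annotations.csv --start 2021-01-01T00:00 \
    --window 62 --format svg --out demo/display.svg
9 points in 62 bins (2 months schedule) -> demo/display.svg
```

The 62-day request selects the 2-month schedule row (1-day bins, cap 62 —
the longest two-month span, July + August, has exactly 62 days). The
`nascence` preset produces weekly home readings with occasional office
visits, so only 9 of the 62 daily bins hold a point; the first reading is an
office visit (square symbol) whose mean of 138/81 mmHg sits near the top of
the systolic goal band. `--format html` emits the interactive version with
the scrubber and hover annotations; `--format json` emits the resolved,
renderer-independent display model.

The same pipeline is available as a library:

```python
from bpviz import build_display_model, render_svg, DisplayConfig
model = build_display_model(measurements, meds, annotations,
                            DisplayConfig(window=(start, end)))
svg = render_svg(model)
```

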