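# Methods

This note records the models, parameters, and numerical choices behind
`bpviz`, and what the synthetic-data tests do and do not establish about real
monitoring streams.

## Domain model

A measurement is a timestamped (systolic, diastolic) pair in mmHg with a
source (`home`, `office`, `inpatient`, `other`) and a `confirmed` flag
(home cuff and technique validated by clinic staff). Validation enforces
systolic > diastolic and physiologic plausibility bounds of 30–300 mmHg —
wide enough to accept genuine hypertensive crises, tight enough to reject
data-entry garbage; the bounds are arguments, not clinical judgement.
Timestamps are timezone-naive local clinic time: the display's semantics are
calendar-local and no DST arithmetic is attempted. 24-h ambulatory readings
are accepted by the parsers and mapped to `home` (they are self-measured
out-of-office values); the mapping is flagged in the parse warnings so a
deployment can revisit it.

The final display uses exactly two marker shapes — circles for home, squares
for everything clinical. Inpatient and other sources therefore render with
the office square; high-density inpatient clusters remain recognizable by
density alone and are not pre-thinned before binning.

## Density schedule

The display caps any view at 62 points. The schedule maps a requested window
length to a bin width and row cap:

| window ≤ | bin width | cap |
|---|---|---|
| 1 day | 30 min | 48 |
| 1 week | 3 h | 56 |
| 2 weeks | 6 h | 56 |
| 1 month | 12 h | 62 |
| 2 months | 1 day | 62 |
| 4 months | 2 days | 62 |
| 6 months | 3 days | 62 |
| 1 year | 7 days | 54 |
| 2 years | 14 days | 54 |
| 5 years | 1 month | 60 |
| 10 years | 2 months | 60 |
| 15 years | 4 months | 60 |
| 30 years | 6 months | 60 |
| 60 years | 1 year | 60 |

Unlisted window lengths snap **up** to the smallest row that covers them (a
10-day request uses the 2-week row), which is what guarantees the caps. Row
thresholds are the worst-case calendar span in days (62 for two months —
July + August; 123 for four; 184 for six; 366 days / 54 distinct weeks for a
year).

Bins are half-open `[start, start+w)` intervals **anchored at the window
start**, not calendar-aligned: calendar alignment can overflow a cap by one
bin for windows that straddle a boundary, while anchored bins make the cap a
theorem. Year-scale rows use 7-day bins from the window start rather than
calendar weeks for the same reason (calendar weeks and the window anchor
cannot both be honored; the 54 cap still holds). Month-unit bin widths step
calendar months from the anchor with day-of-month clamping. One rare
alignment (a maximal-length month-binned window whose anchor sits just after
a leap day) would need one bin over the cap; `plan_bins` then advances to
the next schedule row, so the global ≤ 62 invariant is unconditional.

Aggregation is the **arithmetic mean** per channel (the robust-trend job
belongs to the LOWESS layer, not the binning statistic). Means are kept
unrounded internally and rounded half-up only at presentation. A bin's
marker is a circle when home readings are the strict majority of its
members; ties go to the office square, office readings being
staff-validated. Readings on a bin boundary belong to the later bin
(half-open partition), so every in-window reading contributes to exactly one
point and the count-weighted mean of points equals the raw grand mean to
floating-point accuracy.

## Missing data

For each maximal run of L empty bins between two plotted points, the
bridging segment is dashed iff `L / n_bins > threshold` (default 0.10), else
solid. Two choices were genuinely open:

- the run fraction is measured against the **total window bin count**, the
  closest reading of "consecutive data points missing" at display density —
  not against a gap-local neighborhood;
- the comparison is **strict**: a run of exactly 10% renders solid, since
  the rule is stated as "< 10%" vs "> 10%" with equality unspecified.

Both are config-visible and the tests pin the transition: on a 62-bin window
the flip happens between runs of 6 (9.7%) and 7 (11.3%), bracketing 10%.
Leading/trailing empty runs have no bridge to style; they simply leave the
plot and table empty there.

## LOWESS

Cleveland's procedure, implemented directly: at each point a degree-1
weighted least-squares fit over the contiguous `ceil(frac·n)` nearest
neighbors, tricube weights `(1−(d/dmax)³)³`, then `robust_iterations`
bisquare passes (`(1−(r/6s)²)²`, `s = median|r|`; a zero `s` short-circuits —
the fit is already exact). Defaults `frac = 0.30`,
`robust_iterations = 2`: at 50–62 displayed points a 30% neighborhood spans
roughly 15–19 points, wide enough to show the multi-week trend and narrow
enough to follow a medication response; the robustness passes do the
outlier de-emphasis that motivates the layer. The abscissa is numeric time
in days since window start, so neighborhoods are time-based and span
missing-data gaps with honest distances. Home and office points are smoothed
together, one curve per channel, on the aggregated bin means — the curve and
the raw line must share abscissae for the faded-raw / salient-smooth
layering. Degenerate inputs (fewer than 2 points, or `ceil(frac·n) < 2`, or
a zero-spread neighborhood) disable smoothing; the raw line then renders at
full opacity.

The test suite checks the implementation against two independent references:
a brute-force per-point WLS oracle written in the tests, and statsmodels'
`lowess`; both agree to better than 1e-6 on seeded 200-point series.

## Display resolution and rendering

Goal bounds are **inclusive** (140/90 is in range for the 90–140 / 60–90
default) — configurable, since guideline phrasing ("below 140") is
ambiguous at the boundary. A table cell is bold iff its channel is out of
range or the point aggregates > 1 reading. The y-axis always contains both
goal bands plus a 5 mmHg pad, never autoscaled away. Annotations sharing a
date stack into one marker with concatenated texts. Medication lanes are
keyed by drug name and ordered by first start date; clipping a course to the
window cannot change its lane.

Rendering is deterministic string templating: no timestamps, floats at 3
decimals, stable element order — identical models produce byte-identical
output, which the snapshot tests rely on. Theme numbers the design leaves
qualitative were fixed once and exposed in `RenderTheme`: band fill at alpha
0.18 ("pastel"), raw line at opacity 0.45 ("faded slightly") under a
full-opacity 2.5 px smooth line. Static SVG appends a numbered annotation
footnote list so printing loses no information; HTML adds CSS-hover
annotation bubbles and a small inline script for the scrubber — no charting
framework, so the file stays archival and works offline. Every panel carries
identical `data-t0/t1/x0/x1` attributes declaring the one shared x-scale.

## Synthetic generator

Per reading: `SBP = baseline + circadian + AR(1) + ε + office_offset·1[office]
+ outlier + med(t)`, with the diastolic channel coupled as
`DBP = baseline_dbp + 0.62·(systemic deviation) + ε_d`. The 0.62 coupling
keeps the two channels mutually consistent (and SBP > DBP) without a
hemodynamic model, while guaranteeing that a zero-noise series is exactly
constant at the configured baseline — the anchor the exactness tests use.
Defaults describe a patient with managed stage-1 hypertension on twice-daily
monitoring: baseline 135/85 mmHg, circadian half-swing 8 mmHg peaking
mid-morning, AR(1) with lag-1 correlation 0.6 and stationary SD equal to the
white-noise SD of 6 mmHg, white-coat office offset +8 mmHg, outliers at rate
0.01 and size 25 mmHg. Medication effects are sigmoidal SBP drops of the
configured size beginning at course start + onset delay (default 7 days)
with a 3-day ramp. All randomness derives from one seed through fixed
per-component substreams, so adding a generator feature never shifts
existing draws. Presets mirror the three data-density eras: `dearth`
(office-only, quarterly), `nascence` (weekly home readings), `abundance`
(10-minute cadence).

What the generator does **not** emulate: measurement rounding to cuff
resolution, irregular self-selected measurement times (readings are strictly
cadence-spaced), seasonal trends, arm/posture artifacts, or any
physiologically validated BP dynamics. Passing tests therefore establish the
pipeline's arithmetic and contracts, not clinical realism of the inputs.

## Problem sizes

The test suite and the acceptance script run at the display's native scales:
62-bin windows, 144–2 000-reading synthetic series, 200-point smoothing
series, exhaustive enumeration over two calendar years of start dates — the
scales the schedule itself is defined on. Parameter-recovery checks use
500 office/home pairs and ~1 800 readings around a medication start, enough
for the 2-standard-error criteria to be meaningful.

## Known limitations

- The FHIR reader targets R4 Observation/Bundle shapes only; source and
  confirmed-status mappings (a `measurement-setting` extension, then
  category codings, defaulting to office) are documented conventions, not
  standards — no standard FHIR field records either fact.
- Medication doses are rendered as text labels; no numeric dose-intensity
  encoding.
- No confidence band on the LOWESS curve and no alternative kernels.
- Windows beyond 60 years are unsupported by the schedule.
- The interactive scrubber requires a browser with basic SVG DOM scripting;
  the SVG output is the no-script fallback.
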