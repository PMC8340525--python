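"""Density schedule, bin construction, aggregation, and missing-data styles."""

import math
from datetime import datetime, timedelta

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bpviz.aggregate import (
    GLOBAL_POINT_CAP,
    SCHEDULE,
    _add_months,
    AggregatedPoint,
    LineStyle,
    NonPositiveWindow,
    NoPoints,
    aggregate_measurements,
    classify_segments,
    make_bins,
    plan_bins,
    select_bin_schedule,
)
from bpviz.model import Source

from .conftest import T0, reading


class TestSelectBinSchedule:
    @pytest.mark.parametrize(
        "days,label,width,cap",
        [
            (1, "1 day", "30 minutes", 48),
            (7, "1 week", "3 hours", 56),
            (14, "2 weeks", "6 hours", 56),
            (31, "1 month", "12 hours", 62),
            (62, "2 months", "1 day", 62),
            (123, "4 months", "2 days", 62),
            (184, "6 months", "3 days", 62),
            (366, "1 year", "7 days", 54),
            (731, "2 years", "14 days", 54),
            (1827, "5 years", "1 month", 60),
            (3653, "10 years", "2 months", 60),
            (5479, "15 years", "4 months", 60),
            (10958, "30 years", "6 months", 60),
            (21915, "60 years", "12 months", 60),
        ],
    )
    def test_every_schedule_row(self, days, label, width, cap):
        row = select_bin_schedule(timedelta(days=days))
        assert row.window_label == label
        assert str(row.bin_width) == width
        assert row.max_points == cap

    def test_unlisted_window_snaps_up(self):
        # 10 days falls between the 1-week and 2-week rows
        row = select_bin_schedule(timedelta(days=10))
        assert row.window_label == "2 weeks"
        assert str(row.bin_width) == "6 hours"
        assert row.max_points == 56

    def test_nonpositive_window_rejected(self):
        with pytest.raises(NonPositiveWindow):
            select_bin_schedule(timedelta(0))

    def test_caps_are_from_the_allowed_set(self):
        assert {r.max_points for r in SCHEDULE} == {48, 54, 56, 60, 62}


class TestMakeBins:
    def test_july_august_daily_bins_number_62(self):
        # the longest two-month span of the calendar
        window = (datetime(2021, 7, 1), datetime(2021, 9, 1))
        row = select_bin_schedule(window[1] - window[0])
        bins = make_bins(window, row)
        assert len(bins) == 62
        assert bins[0][0] == window[0]
        assert bins[-1][1] == window[1]

    def test_one_day_gives_48_half_hour_bins(self):
        window = (T0, T0 + timedelta(days=1))
        bins = make_bins(window, select_bin_schedule(timedelta(days=1)))
        assert len(bins) == 48
        assert all(b - a == timedelta(minutes=30) for a, b in bins)

    def test_bins_are_half_open_and_contiguous(self):
        window = (T0, T0 + timedelta(days=10))
        bins = make_bins(window, select_bin_schedule(timedelta(days=10)))
        for (a1, b1), (a2, b2) in zip(bins, bins[1:]):
            assert b1 == a2

    def test_degenerate_window_rejected(self):
        with pytest.raises(NonPositiveWindow):
            make_bins((T0, T0), select_bin_schedule(timedelta(days=1)))

    def test_month_bins_step_the_calendar(self):
        window = (datetime(2020, 1, 31), datetime(2025, 1, 30))
        row = select_bin_schedule(window[1] - window[0])
        bins = make_bins(window, row)
        assert row.window_label == "5 years"
        assert len(bins) <= 60
        # day-of-month clamped in short months
        assert bins[0][1] == datetime(2020, 2, 29)

    def test_plan_bins_never_exceeds_global_cap(self):
        # worst leap-edge alignments included
        for start in (datetime(2020, 3, 1), datetime(2019, 2, 28)):
            for days in (62, 123, 184, 366, 1827, 3653, 10958):
                _, bins = plan_bins((start, start + timedelta(days=days)))
                assert len(bins) <= GLOBAL_POINT_CAP


def _dense_series(window, step):
    out = []
    t, i = window[0], 0
    while t < window[1]:
        out.append(reading(hours=(t - T0).total_seconds() / 3600, sbp=120 + (i % 7), dbp=78 + (i % 5)))
        t += step
        i += 1
    return out


class TestAggregateMeasurements:
    def test_two_member_bin_means(self):
        window = (T0, T0 + timedelta(days=1))
        bins = make_bins(window, select_bin_schedule(timedelta(days=1)))
        ms = [reading(hours=0.1, sbp=120, dbp=80), reading(hours=0.2, sbp=130, dbp=90)]
        (p,) = aggregate_measurements(ms, bins)
        assert (p.mean_systolic, p.mean_diastolic) == (125.0, 85.0)
        assert p.n_measurements == 2 and p.is_aggregate

    def test_single_home_reading_keeps_circle_symbol(self):
        window = (T0, T0 + timedelta(days=1))
        bins = make_bins(window, select_bin_schedule(timedelta(days=1)))
        (p,) = aggregate_measurements([reading(hours=1, sbp=118, dbp=76)], bins)
        assert p.source_symbol == "circle_home"
        assert not p.is_aggregate
        assert (p.mean_systolic, p.mean_diastolic) == (118.0, 76.0)

    @pytest.mark.parametrize(
        "sources,symbol",
        [
            ([Source.HOME, Source.HOME, Source.OFFICE], "circle_home"),
            ([Source.HOME, Source.OFFICE], "square_office"),  # tie -> office
            ([Source.OFFICE], "square_office"),
            ([Source.INPATIENT], "square_office"),  # clinical sources use the square
        ],
    )
    def test_majority_source_symbol(self, sources, symbol):
        window = (T0, T0 + timedelta(days=1))
        bins = make_bins(window, select_bin_schedule(timedelta(days=1)))
        ms = [
            reading(hours=0.1 * i, source=s) for i, s in enumerate(sources)
        ]
        (p,) = aggregate_measurements(ms, bins)
        assert p.source_symbol == symbol

    def test_ten_minute_cadence_day_gives_three_per_bin(self):
        window = (T0, T0 + timedelta(days=1))
        bins = make_bins(window, select_bin_schedule(timedelta(days=1)))
        ms = _dense_series(window, timedelta(minutes=10))
        points = aggregate_measurements(ms, bins)
        assert len(points) == 48
        assert all(p.n_measurements == 3 for p in points)

    def test_grand_mean_is_conserved(self, two_month_series):
        window = (T0, T0 + timedelta(days=62))
        _, bins = plan_bins(window)
        points = aggregate_measurements(two_month_series, bins)
        for chan, attr in (("systolic", "mean_systolic"), ("diastolic", "mean_diastolic")):
            raw = [getattr(m, chan) for m in two_month_series]
            weighted = sum(p.n_measurements * getattr(p, attr) for p in points)
            n = sum(p.n_measurements for p in points)
            assert n == len(raw)
            assert abs(weighted / n - sum(raw) / len(raw)) < 1e-9

    def test_each_reading_lands_in_exactly_one_bin(self, two_month_series):
        window = (T0, T0 + timedelta(days=62))
        _, bins = plan_bins(window)
        points = aggregate_measurements(two_month_series, bins)
        assert sum(p.n_measurements for p in points) == len(two_month_series)
        for p in points:
            a, b = p.bin_interval
            members = [m for m in two_month_series if a <= m.timestamp < b]
            assert len(members) == p.n_measurements
            assert min(m.systolic for m in members) <= p.mean_systolic <= max(
                m.systolic for m in members
            )

    def test_boundary_reading_goes_to_later_bin(self):
        window = (T0, T0 + timedelta(days=1))
        bins = make_bins(window, select_bin_schedule(timedelta(days=1)))
        (p,) = aggregate_measurements([reading(hours=0.5)], bins)  # exactly bin 1 start
        assert p.bin_index == 1


def _points_at(indices, bins):
    return [
        AggregatedPoint(
            bin_index=i,
            bin_interval=bins[i],
            mean_systolic=125.0,
            mean_diastolic=80.0,
            n_measurements=1,
            source_symbol="circle_home",
        )
        for i in sorted(indices)
    ]


def _bins62():
    return make_bins((T0, T0 + timedelta(days=62)), select_bin_schedule(timedelta(days=62)))


class TestClassifySegments:
    def test_small_gap_of_5_in_62_bins_stays_solid(self):
        bins = _bins62()
        occupied = [i for i in range(62) if not 20 <= i < 25]
        segs = classify_segments(_points_at(occupied, bins), 62, 0.10)
        assert all(s.style is LineStyle.SOLID for s in segs)

    def test_large_gap_of_10_in_62_bins_goes_dashed(self):
        bins = _bins62()
        occupied = [i for i in range(62) if not 20 <= i < 30]
        segs = classify_segments(_points_at(occupied, bins), 62, 0.10)
        dashed = [s for s in segs if s.style is LineStyle.DASHED]
        assert len(dashed) == 1
        assert dashed[0].span == (19, 30)

    def test_no_gaps_gives_single_solid_polyline(self):
        bins = _bins62()
        segs = classify_segments(_points_at(range(62), bins), 62, 0.10)
        assert len(segs) == 61
        assert all(s.style is LineStyle.SOLID for s in segs)

    def test_style_change_brackets_ten_percent(self):
        # scanning run lengths, the solid->dashed transition straddles
        # exactly 10% of the window's bins
        bins = _bins62()
        styles = {}
        for run in range(1, 40):
            occupied = [0] + list(range(run + 1, 62))
            segs = classify_segments(_points_at(occupied, bins), 62, 0.10)
            styles[run] = segs[0].style
        solid_max = max(r for r, s in styles.items() if s is LineStyle.SOLID)
        dashed_min = min(r for r, s in styles.items() if s is LineStyle.DASHED)
        assert dashed_min == solid_max + 1
        assert solid_max / 62 <= 0.10 < dashed_min / 62

    def test_exactly_ten_percent_renders_solid(self):
        # strict > comparison: a run of exactly threshold*n_bins stays solid
        bins = make_bins((T0, T0 + timedelta(days=50)), select_bin_schedule(timedelta(days=62)))
        occupied = [0] + list(range(6, 50))  # run of 5 = 10% of 50
        segs = classify_segments(_points_at(occupied, bins), 50, 0.10)
        assert segs[0].style is LineStyle.SOLID

    def test_no_points_raises(self):
        with pytest.raises(NoPoints):
            classify_segments([], 62, 0.10)

    @settings(deadline=None, max_examples=60)
    @given(mask=st.lists(st.booleans(), min_size=2, max_size=62).filter(lambda m: sum(m) >= 2))
    def test_styles_depend_only_on_the_empty_bin_mask(self, mask):
        bins = make_bins(
            (T0, T0 + timedelta(days=len(mask))),
            select_bin_schedule(timedelta(days=62)),
        )
        idx = [i for i, occ in enumerate(mask) if occ]
        pts1 = _points_at(idx, bins)
        # permute values inside bins: styles must not change
        pts2 = [
            AggregatedPoint(
                bin_index=p.bin_index,
                bin_interval=p.bin_interval,
                mean_systolic=200.0 - i,
                mean_diastolic=40.0 + i,
                n_measurements=3,
                source_symbol="square_office",
            )
            for i, p in enumerate(pts1)
        ]
        s1 = classify_segments(pts1, len(mask), 0.10)
        s2 = classify_segments(pts2, len(mask), 0.10)
        assert [(s.span, s.style) for s in s1] == [(s.span, s.style) for s in s2]

    @settings(deadline=None, max_examples=60)
    @given(
        mask=st.lists(st.booleans(), min_size=3, max_size=62).filter(lambda m: sum(m) >= 2),
        data=st.data(),
    )
    def test_filling_an_empty_bin_never_creates_a_dash(self, mask, data):
        empties = [i for i, occ in enumerate(mask) if not occ]
        if not empties:
            return
        fill = data.draw(st.sampled_from(empties))
        bins = make_bins(
            (T0, T0 + timedelta(days=len(mask))),
            select_bin_schedule(timedelta(days=62)),
        )
        before = classify_segments(
            _points_at([i for i, o in enumerate(mask) if o], bins), len(mask), 0.10
        )
        mask2 = list(mask)
        mask2[fill] = True
        after = classify_segments(
            _points_at([i for i, o in enumerate(mask2) if o], bins), len(mask), 0.10
        )
        # a segment lying inside a previously solid bridge must stay solid;
        # (a previously dashed bridge may split into shorter solid pieces,
        # and filling a leading/trailing bin may create a brand-new bridge)
        solid_spans = [s.span for s in before if s.style is LineStyle.SOLID]
        for s in after:
            if any(A <= s.span[0] < s.span[1] <= B for A, B in solid_spans):
                assert s.style is LineStyle.SOLID


class TestGlobalCap:
    @pytest.mark.parametrize("row", SCHEDULE, ids=lambda r: r.window_label)
    def test_dense_input_never_exceeds_row_cap(self, row):
        if row.bin_width.is_calendar:
            # month-unit rows: the row's span is a calendar span
            years = int(row.window_label.split()[0])
            window = (T0, _add_months(T0, 12 * years))
        else:
            window = (T0, T0 + timedelta(days=row.max_window_days))
        bins = make_bins(window, row)
        assert len(bins) <= row.max_points <= GLOBAL_POINT_CAP
        # every bin occupied -> point count equals bin count, still capped
        ms = [reading(hours=(a - T0).total_seconds() / 3600 + 0.001) for a, _ in bins]
        points = aggregate_measurements(ms, bins)
        assert len(points) == len(bins) <= GLOBAL_POINT_CAP
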