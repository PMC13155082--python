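"""Intensity bands, activity summaries, change points, sedentary events."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metwear import (
    IntensityLevel,
    classify_intensity,
    detect_changepoints,
    detect_sedentary_events,
    find_sleep_period,
    sedentary_constants,
    segment_sleep,
    summarize_activity,
)


class TestClassifyIntensity:
    @pytest.mark.parametrize(
        "met, level",
        [
            (0.95, IntensityLevel.SLEEP),
            (1.0, IntensityLevel.SEDENTARY),
            (1.6, IntensityLevel.LIGHT),
            (3.0, IntensityLevel.MODERATE),
            (6.0, IntensityLevel.VIGOROUS),
            (12.0, IntensityLevel.VIGOROUS),
        ],
    )
    def test_half_open_bands(self, met, level):
        assert classify_intensity(met) == level

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            classify_intensity(0.0)

    @given(st.floats(min_value=0.01, max_value=20), st.floats(min_value=0.0, max_value=5))
    @settings(deadline=None)
    def test_monotone_in_met(self, met, bump):
        assert classify_intensity(met + bump).value >= classify_intensity(met).value


class TestSummarizeActivity:
    def test_one_hour_of_sleep(self):
        s = summarize_activity(np.full(360_000, 0.95), "P100")
        assert s.total_hours == 1.0
        assert s.hours[IntensityLevel.SLEEP] == 1.0
        assert sum(v for k, v in s.hours.items() if k != IntensityLevel.SLEEP) == 0.0

    def test_empty_series(self):
        s = summarize_activity(np.empty(0))
        assert s.total_hours == 0.0 and all(v == 0 for v in s.hours.values())

    def test_additive_under_concatenation(self):
        rng = np.random.default_rng(0)
        a, b = rng.uniform(0.5, 8.0, 500), rng.uniform(0.5, 8.0, 700)
        sa, sb = summarize_activity(a), summarize_activity(b)
        sc = summarize_activity(np.concatenate([a, b]))
        for level in IntensityLevel:
            assert sc.hours[level] == pytest.approx(sa.hours[level] + sb.hours[level], abs=1e-12)

    def test_conserves_total_time(self):
        rng = np.random.default_rng(1)
        met = rng.uniform(0.3, 9.0, 12_345)
        s = summarize_activity(met)
        assert sum(s.hours.values()) == pytest.approx(s.total_hours, abs=1e-9)

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError):
            summarize_activity(np.array([1.0, np.nan]))


class TestSedentaryConstants:
    def test_thirty_minutes(self):
        assert sedentary_constants(10_000, 100, 30) == (180_000, 18)

    def test_sixty_minutes(self):
        assert sedentary_constants(10_000, 100, 60) == (360_000, 36)

    def test_unit_window(self):
        assert sedentary_constants(1, 100, 30) == (180_000, 180_000)

    def test_non_divisible_warns_and_rounds_down(self):
        with pytest.warns(UserWarning):
            _, ws = sedentary_constants(7_000, 100, 30)
        assert ws == 180_000 // 7_000


class TestDetectChangepoints:
    def test_constant_series_no_detections(self):
        cps = detect_changepoints(np.full(50, 2.0), k=3, lam=0)
        assert len(cps.indices) == 0

    def test_single_step_detected_once(self):
        series = np.concatenate([np.full(100, 1.0), np.full(100, 5.0)])
        cps = detect_changepoints(series, k=3, lam=0, refractory=0)
        np.testing.assert_array_equal(cps.indices, [100])

    def test_lambda_raises_threshold_after_detection(self):
        series = np.concatenate([np.full(50, 1.0), np.full(50, 5.0), np.full(50, 9.0)])
        lam0 = detect_changepoints(series, k=1, lam=0.0, refractory=0)
        lam5 = detect_changepoints(series, k=1, lam=0.5, refractory=0)
        assert len(lam0.indices) >= len(lam5.indices)
        # the threshold trace never decreases once a detection occurred
        first = lam5.indices[0] - 1
        assert np.all(np.diff(lam5.thresholds[first:]) >= 0)

    def test_shift_invariance_at_lambda_zero(self):
        rng = np.random.default_rng(0)
        series = np.cumsum(rng.normal(size=200))
        a = detect_changepoints(series, k=2, lam=0, refractory=0)
        b = detect_changepoints(series + 42.0, k=2, lam=0, refractory=0)
        np.testing.assert_array_equal(a.indices, b.indices)

    def test_positive_scale_invariance(self):
        rng = np.random.default_rng(1)
        series = np.cumsum(rng.normal(size=200))
        a = detect_changepoints(series, k=2, lam=0, refractory=0)
        b = detect_changepoints(series * 3.7, k=2, lam=0, refractory=0)
        np.testing.assert_array_equal(a.indices, b.indices)

    def test_refractory_skips_neighbouring_positions(self):
        series = np.concatenate([np.zeros(50), [10.0, 0.0, 10.0], np.zeros(50)])
        cps = detect_changepoints(series, k=1, lam=0, refractory=3)
        assert list(cps.indices) == [50]

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            detect_changepoints(np.array([1.0, 2.0]))


class TestSegmentSleep:
    def test_no_changepoints_single_segment(self):
        series = np.ones(100)
        cps = detect_changepoints(series, k=3)
        seg = segment_sleep(series, cps)
        assert len(seg.segments) == 1
        assert seg.segments[0].duration_hours == pytest.approx(seg.total_sleep_hours)

    def test_two_changepoints_three_segments_telescope(self):
        series = np.concatenate([np.zeros(40), np.full(30, 5.0), np.zeros(50)])
        cps = detect_changepoints(series, k=1, lam=0, refractory=0)
        seg = segment_sleep(series, cps)
        assert len(seg.segments) == len(cps.indices) + 1
        assert sum(s.duration_hours for s in seg.segments) == pytest.approx(seg.total_sleep_hours)
        assert [s.pattern for s in seg.segments] == list(range(1, len(seg.segments) + 1))

    def test_empty_span(self):
        seg = segment_sleep(np.empty(0), detect_changepoints(np.zeros(10), k=3))
        assert seg.total_sleep_hours == 0 and seg.segments == []


class TestFindSleepPeriod:
    def test_longest_low_run_wins(self):
        met = np.concatenate([np.full(100, 0.9), np.full(50, 2.0), np.full(300, 0.95), np.full(50, 2.0)])
        span = find_sleep_period(met, min_hours=300 / 360_000)
        assert span == (150, 450)

    def test_short_runs_rejected(self):
        met = np.concatenate([np.full(100, 0.9), np.full(100, 2.0)])
        assert find_sleep_period(met, min_hours=2.0) is None


def sedentary_oracle(low, ws):
    """Exhaustive reference: test every interval of length ws, then merge
    qualifying starts into bouts with one alert each."""
    qualifying = [t for t in range(len(low) - ws + 1) if all(low[t : t + ws])]
    events = []
    for t in qualifying:
        if events and t <= events[-1][1] + 1 and all(low[events[-1][0] : t + ws]):
            events[-1] = (events[-1][0], t + ws - 1)
        else:
            events.append((t, t + ws - 1))
    return events


class TestDetectSedentaryEvents:
    def test_exactly_ws_low_windows_is_one_event(self):
        events = detect_sedentary_events(np.full(18, 1.5), ws=18)
        assert len(events) == 1
        assert events[0].start_window == 0 and events[0].onset_sample == 0

    def test_below_duration_criterion_no_event(self):
        mets = np.concatenate([np.full(17, 1.5), [2.0]])
        assert detect_sedentary_events(mets, ws=18) == []

    def test_long_bout_single_alert(self):
        events = detect_sedentary_events(np.full(36, 1.5), ws=18)
        assert len(events) == 1 and events[0].alert_emitted

    def test_threshold_boundary_is_non_sedentary(self):
        assert detect_sedentary_events(np.full(20, 1.6), ws=18) == []

    def test_empty_sequence(self):
        assert detect_sedentary_events(np.empty(0)) == []

    def test_agrees_with_exhaustive_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = int(rng.integers(1, 201))
            ws = int(rng.integers(1, 25))
            low = rng.random(n) < 0.7
            mets = np.where(low, 1.0, 2.0)
            got = [(e.start_window, e.end_window) for e in detect_sedentary_events(mets, ws=ws)]
            exp = sedentary_oracle(low.tolist(), ws)
            assert got == exp

    def test_events_disjoint_and_separated(self):
        rng = np.random.default_rng(5)
        mets = np.where(rng.random(500) < 0.8, 1.2, 3.0)
        events = detect_sedentary_events(mets, ws=5)
        for a, b in zip(events[:-1], events[1:]):
            assert b.start_window > a.end_window + 1
        assert all(e.alert_emitted for e in events)
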