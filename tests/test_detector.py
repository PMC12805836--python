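"""Smoothing, the buffer-zone flip detector, and rate aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scramblekit.errors import ConfigError, InputError
from scramblekit.flip import detect_flip_events, scrambling_rate, smooth_and_resample
from scramblekit.types import DetectorConfig, FlipEvent

from conftest import make_series, oracle_event_count


class TestSmoothing:
    def test_constant_series_preserved(self):
        s = make_series([[170.0] * 200], dt=1.0)
        out = smooth_and_resample(s, DetectorConfig())
        assert np.all(out.angles == pytest.approx(170.0))

    def test_balanced_alternation_averages_to_midpoint(self):
        s = make_series([[160.0, 180.0] * 200], dt=1.0)
        out = smooth_and_resample(s, DetectorConfig())
        interior = out.angles[0, 2:-2]
        np.testing.assert_allclose(interior, 170.0, atol=0.5)

    def test_white_noise_variance_reduced_by_window_length(self):
        rng = np.random.default_rng(3)
        noise = rng.normal(90.0, 10.0, size=(1, 10_000))
        s = make_series(noise, dt=1.0)
        out = smooth_and_resample(s, DetectorConfig())
        interior = out.angles[0, 2:-2]
        ratio = interior.var() / noise.var()
        assert 0.8 / 50 < ratio < 1.2 / 50

    def test_invalid_samples_excluded_from_mean(self):
        a = np.full((1, 100), 100.0)
        a[0, 40:60] = 5000.0  # poison, but masked invalid
        v = np.ones_like(a, dtype=bool)
        v[0, 40:60] = False
        out = smooth_and_resample(make_series(a, dt=1.0, valid=v), DetectorConfig())
        assert np.all(out.angles[out.valid] == pytest.approx(100.0))

    def test_output_times_are_window_centers_on_stride(self):
        s = make_series([np.arange(200.0)], dt=1.0)
        out = smooth_and_resample(s, DetectorConfig())
        np.testing.assert_array_equal(out.times, np.arange(0.0, 200.0, 25.0))

    def test_window_shorter_than_two_samples_rejected(self):
        s = make_series([[10.0] * 10], dt=100.0)
        with pytest.raises(ConfigError):
            smooth_and_resample(s, DetectorConfig(smooth_window=100.0,
                                                  resample_stride=100.0))


class TestDetector:
    def test_single_clean_crossing(self):
        s = make_series([np.linspace(10.0, 170.0, 30)])
        events = detect_flip_events(s)
        assert len(events) == 1
        ev = events[0]
        assert ev.direction == "down->up"
        assert ev.start_ns < ev.end_ns
        # start is the last sample below 55, end the first above 125
        assert s.angles[0, int(ev.start_ns / 25)] < 55
        assert s.angles[0, int(ev.end_ns / 25)] > 125

    def test_buffer_oscillation_counts_nothing(self):
        # repeated excursions into the buffer that fall back are not events
        s = make_series([[30.0, 100.0, 30.0, 100.0, 30.0]])
        assert detect_flip_events(s) == []

    def test_buffer_start_defers_initial_zone(self):
        # first non-buffer sample defines the committed zone: no event for
        # buffer -> B, one event for buffer -> B -> A
        assert detect_flip_events(make_series([[90.0, 100.0, 160.0]])) == []
        evs = detect_flip_events(make_series([[90.0, 160.0, 160.0, 20.0]]))
        assert len(evs) == 1 and evs[0].direction == "up->down"

    def test_all_buffer_series_yields_no_events(self):
        assert detect_flip_events(make_series([[90.0] * 10])) == []

    def test_event_timing_convention(self):
        s = make_series([[20.0, 20.0, 90.0, 90.0, 160.0, 160.0]])
        (ev,) = detect_flip_events(s)
        assert ev.start_ns == 25.0  # last sample committed below
        assert ev.end_ns == 100.0  # first sample committed above

    def test_consecutive_events_alternate_direction(self):
        s = make_series([[20, 160, 20, 160, 20]])
        evs = detect_flip_events(s)
        assert [e.direction for e in evs] == [
            "down->up", "up->down", "down->up", "up->down",
        ]

    @given(
        st.lists(
            st.sampled_from([10.0, 40.0, 70.0, 90.0, 110.0, 140.0, 170.0]),
            min_size=0, max_size=12,
        )
    )
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_equivalence_with_collapse_oracle(self, angles):
        if not angles:
            return
        evs = detect_flip_events(make_series([angles]))
        assert len(evs) == oracle_event_count(angles)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=180.0,
                           allow_nan=False), min_size=1, max_size=30)
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_oracle_equivalence_on_arbitrary_angles(self, angles):
        evs = detect_flip_events(make_series([angles]))
        assert len(evs) == oracle_event_count(angles)
        for a, b in zip(evs, evs[1:]):
            assert a.direction != b.direction

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(11)
        angles = rng.uniform(0, 180, size=(5, 300))
        base_cfg = DetectorConfig()
        n_base = len(detect_flip_events(make_series(angles), base_cfg))
        for lo, hi in [(55, 140), (40, 125), (30, 150)]:
            n = len(
                detect_flip_events(
                    make_series(angles),
                    DetectorConfig(lower_threshold=lo, upper_threshold=hi),
                )
            )
            if lo <= 55 and hi >= 125:
                assert n <= n_base or (lo == 55 and hi == 125)
        # widening the buffer can only reduce the count
        n_wide = len(
            detect_flip_events(
                make_series(angles),
                DetectorConfig(lower_threshold=30, upper_threshold=150),
            )
        )
        assert n_wide <= n_base

    def test_time_translation_and_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        angles = rng.uniform(0, 180, size=(4, 100))
        s1 = make_series(angles)
        s2 = make_series(angles)
        s2.times = s2.times + 12_345.0
        s2.lipid_ids = s2.lipid_ids + 40
        e1, e2 = detect_flip_events(s1), detect_flip_events(s2)
        assert len(e1) == len(e2)
        for a, b in zip(e1, e2):
            assert b.start_ns - a.start_ns == pytest.approx(12_345.0)
            assert b.lipid_id - a.lipid_id == 40
            assert a.direction == b.direction

    def test_invalid_samples_are_skipped_not_zoned(self):
        a = np.array([[20.0, 0.0, 160.0]])
        v = np.array([[True, False, True]])
        evs = detect_flip_events(make_series(a, valid=v))
        assert len(evs) == 1


class TestRates:
    def test_zero_events_zero_rate(self):
        r = scrambling_rate([[]], [10.0])
        assert r.mean == 0.0 and r.total_events == 0

    def test_replicate_arithmetic(self):
        ev = lambda n: [
            FlipEvent(lipid_id=i, start_ns=10.0 * i, end_ns=10.0 * i + 1,
                      direction="up->down" if i % 2 else "down->up")
            for i in range(n)
        ]
        r = scrambling_rate([ev(46), ev(46), ev(46)], [10.0, 10.0, 10.0])
        assert r.mean == pytest.approx(4.6)
        assert r.total_events == 138
        assert r.total_time_us == pytest.approx(30.0)
        assert r.sd == 0.0

    def test_mean_equals_pooled_for_equal_durations(self):
        ev = lambda n: [
            FlipEvent(lipid_id=i, start_ns=float(i), end_ns=i + 1.0,
                      direction="down->up")
            for i in range(n)
        ]
        r = scrambling_rate([ev(3), ev(7), ev(5)], [2.0, 2.0, 2.0])
        assert r.mean == pytest.approx(r.total_events / r.total_time_us)

    def test_unit_invariance_ns_vs_us(self):
        ev = [
            FlipEvent(lipid_id=0, start_ns=1.0, end_ns=2.0, direction="down->up")
        ] * 5
        r_us = scrambling_rate([ev], [10.0], time_unit="us")
        r_ns = scrambling_rate([ev], [10_000.0], time_unit="ns")
        assert r_us.mean == pytest.approx(r_ns.mean)
        assert r_us.total_time_us == pytest.approx(r_ns.total_time_us)

    def test_empty_replicate_list_rejected(self):
        with pytest.raises(InputError):
            scrambling_rate([], [])
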