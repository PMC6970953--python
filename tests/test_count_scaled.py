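"""Count-scaled scorer: scaling, weighted-window classification, event
run-length rules, flag-anchored onset/offset location — checked against
worked examples and a brute-force event oracle."""

from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actisleep.core import AlgorithmConfig, CoverageError, ValidationError
from actisleep.count_scaled import (
    SleepEventList,
    aggregate_to_minutes,
    classify_sleep_wake,
    detect_events,
    locate_sleep_offset,
    locate_sleep_onset,
    scale_counts,
    score_night,
    weighted_activity,
    weighted_activity_profile,
)

from conftest import T0, deterministic_night, make_series, minute_labels


def brute_force_events(asleep, sleep_run=15, wake_run=5):
    """Literal index scan over the run-length definitions (the oracle)."""
    n = len(asleep)
    onsets, wakes = [], []
    for i in range(n):
        if (
            i - wake_run >= 0
            and i + sleep_run <= n
            and all(asleep[i : i + sleep_run])
            and not any(asleep[i - wake_run : i])
        ):
            onsets.append(i)
        if (
            i - sleep_run + 1 >= 0
            and i + wake_run < n
            and all(asleep[i - sleep_run + 1 : i + 1])
            and not any(asleep[i + 1 : i + 1 + wake_run])
        ):
            wakes.append(i)
    return onsets, wakes


class TestAggregateToMinutes:
    def test_sums_four_quarter_minute_epochs(self):
        m = aggregate_to_minutes(make_series([10, 20, 30, 40]))
        assert list(m.values) == [100]

    def test_zeros_stay_zero(self):
        m = aggregate_to_minutes(make_series([0] * 8))
        assert list(m.values) == [0, 0]

    def test_partial_trailing_minute_dropped(self):
        m = aggregate_to_minutes(make_series([1, 1, 1, 1, 2, 2, 2]))
        assert list(m.values) == [4]

    def test_minute_epochs_pass_through(self):
        m = aggregate_to_minutes(make_series([5, 7], epoch_length_s=60))
        assert list(m.values) == [5, 7]

    def test_sub_minute_series_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_to_minutes(make_series([1, 2, 3]))


class TestScaleCounts:
    def test_constant_input_scales_to_one(self):
        sc = scale_counts(aggregate_to_minutes(make_series([3] * 12)))
        assert sc.scale_factor == 12.0
        assert np.allclose(sc.scaled, 1.0)

    def test_zero_values_excluded_from_the_mean(self):
        sc = scale_counts(
            aggregate_to_minutes(make_series([0, 0, 0, 0, 2, 0, 0, 0, 4, 0, 0, 0]))
        )
        assert sc.scale_factor == 3.0
        assert np.allclose(sc.scaled, [0.0, 2 / 3, 4 / 3])

    def test_all_zero_recording_scales_by_identity(self):
        sc = scale_counts(aggregate_to_minutes(make_series([0] * 8)))
        assert sc.scale_factor == 1.0
        assert np.all(sc.scaled == 0)


class TestWeightedActivity:
    def test_zero_everywhere(self, config):
        sc = scale_counts(aggregate_to_minutes(make_series([0] * 40)))
        assert all(
            weighted_activity(sc, t, config) == 0.0 for t in range(len(sc))
        )

    def test_constant_series_gives_the_weight_total(self, config):
        sc = scale_counts(aggregate_to_minutes(make_series([5] * 40)))
        profile = weighted_activity_profile(sc, config)
        assert np.allclose(profile, 1.0)  # uniform weights sum to 1

    def test_single_spike_four_minutes_back(self, config):
        # scaled window t-4..t+2 sees [2,0,0,0,0,0,0] -> 2/7 under uniform weights
        minutes = [6.0, 0, 0, 0, 0, 0, 0, 0, 1.5, 1.5]  # non-zero mean 3
        counts = np.repeat([m / 4 for m in minutes], 4)
        sc = scale_counts(aggregate_to_minutes(make_series(counts)))
        assert sc.scaled[0] == pytest.approx(2.0)
        assert weighted_activity(sc, 4, config) == pytest.approx(2 / 7)
        # and 2/7 < 1, so minute 4 is scored sleep
        assert classify_sleep_wake(sc, config).asleep[4]

    def test_edge_truncation_renormalises(self, config):
        sc = scale_counts(aggregate_to_minutes(make_series([5] * 40)))
        # without renormalisation the first minute would see only 3 of 7 weights
        assert weighted_activity(sc, 0, config) == pytest.approx(1.0)


class TestClassify:
    def test_all_zero_is_all_sleep(self, config):
        sc = scale_counts(aggregate_to_minutes(make_series([0] * 40)))
        assert classify_sleep_wake(sc, config).asleep.all()

    def test_constant_scaled_one_is_all_wake(self, config):
        # threshold comparison is strict: 1 is not < 1
        sc = scale_counts(aggregate_to_minutes(make_series([5] * 40)))
        assert not classify_sleep_wake(sc, config).asleep.any()

    def test_provenance_recorded(self, config):
        sc = scale_counts(aggregate_to_minutes(make_series([0] * 8)))
        sw = classify_sleep_wake(sc, config, subject_id="kid7")
        assert sw.algorithm == "count-scaled"
        assert sw.params["threshold"] == config.threshold
        assert sw.subject_id == "kid7"


class TestDetectEvents:
    def test_worked_sequence(self, config):
        seq = [False] * 5 + [True] * 15 + [False] * 5 + [True] * 20
        ev = detect_events(minute_labels(seq), config)
        onsets = [(t - T0).total_seconds() / 60 for t in ev.onset_events]
        wakes = [(t - T0).total_seconds() / 60 for t in ev.wake_events]
        assert onsets == [5, 25]
        assert wakes == [19]

    def test_all_sleep_night_has_no_events(self, config):
        ev = detect_events(minute_labels([True] * 60), config)
        assert ev.onset_events == () and ev.wake_events == ()

    def test_four_preceding_wake_minutes_are_not_enough(self, config):
        ev = detect_events(minute_labels([False] * 4 + [True] * 15), config)
        assert ev.onset_events == ()

    def test_short_series_yield_empty_lists(self, config):
        ev = detect_events(minute_labels([True, False]), config)
        assert ev.onset_events == () and ev.wake_events == ()

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.booleans(), min_size=1, max_size=120))
    def test_matches_brute_force_oracle(self, bits):
        config = AlgorithmConfig()
        ev = detect_events(minute_labels(bits), config)
        on, wk = brute_force_events(bits)
        assert [(t - T0).total_seconds() / 60 for t in ev.onset_events] == on
        assert [(t - T0).total_seconds() / 60 for t in ev.wake_events] == wk


class TestLocateOnsetOffset:
    def mk(self, *minutes):
        return tuple(T0 + timedelta(minutes=m) for m in minutes)

    def test_forward_window_takes_first_event(self, config):
        flag = datetime(2023, 6, 1, 19, 30)
        ev = SleepEventList(self.mk(190, 260), ())  # 20:10 and 21:20
        assert locate_sleep_onset(ev, flag, config) == datetime(2023, 6, 1, 20, 10)

    def test_backward_window_takes_last_event(self, config):
        flag = datetime(2023, 6, 1, 19, 30)
        ev = SleepEventList(self.mk(60), ())  # 18:00 only
        assert locate_sleep_onset(ev, flag, config) == datetime(2023, 6, 1, 18, 0)

    def test_no_events_fall_back_to_the_flag(self, config):
        flag = datetime(2023, 6, 1, 19, 30)
        assert locate_sleep_onset(SleepEventList((), ()), flag, config) == flag

    def test_backward_window_is_half_open_at_the_flag(self, config):
        # an event exactly at the flag is found by the forward pass only
        flag = T0 + timedelta(minutes=150)
        ev = SleepEventList(self.mk(150), ())
        assert locate_sleep_onset(ev, flag, config) == flag

    def test_offset_mirrors_onset_on_wake_events(self, config):
        flag = datetime(2023, 6, 2, 6, 0)
        ev = SleepEventList((), (datetime(2023, 6, 2, 6, 40),))
        assert locate_sleep_offset(ev, flag, config) == datetime(2023, 6, 2, 6, 40)
        ev = SleepEventList((), (datetime(2023, 6, 2, 5, 0),))
        assert locate_sleep_offset(ev, flag, config) == datetime(2023, 6, 2, 5, 0)
        assert locate_sleep_offset(SleepEventList((), ()), flag, config) == flag


class TestScoreNight:
    def test_recovers_transitions_of_a_deterministic_night(self, config):
        series = deterministic_night()
        labels, onset, offset = score_night(series, config)
        assert abs((onset - datetime(2023, 6, 1, 20, 0)).total_seconds()) <= 60
        assert abs((offset - datetime(2023, 6, 2, 6, 30)).total_seconds()) <= 60

    def test_all_zero_recording_falls_back_to_both_flags(self, config):
        series = make_series([0] * (16 * 240))  # 16 h of silence from 17:00
        labels, onset, offset = score_night(series, config)
        assert labels.asleep.all()
        assert onset == datetime(2023, 6, 1, 19, 30)
        assert offset == datetime(2023, 6, 2, 6, 0)

    def test_broadcast_length_is_four_epochs_per_minute(self, config):
        series = make_series([0] * 246)  # 61.5 min; partial minute dropped
        labels, _, _ = score_night(make_series([0] * (16 * 240)), config)
        assert len(labels) == 4 * (len(labels) // 4)
        assert labels.epoch_length_s == 15

    def test_recording_missing_a_flag_is_rejected(self, config):
        with pytest.raises(CoverageError):
            score_night(make_series([0] * 240), config)  # one hour only

    def test_scale_invariance(self, config):
        series = deterministic_night()
        ref_labels, ref_on, ref_off = score_night(series, config)
        for c in (0.25, 3.0, 117.0):
            scaled = make_series(series.counts * c, start=series.start_time)
            labels, on, off = score_night(scaled, config)
            assert np.array_equal(labels.asleep, ref_labels.asleep)
            assert (on, off) == (ref_on, ref_off)

    def test_threshold_monotonicity(self):
        series = deterministic_night()
        prev = None
        for th in (0.5, 1.0, 1.5, 2.5):
            cfg = AlgorithmConfig(threshold=th)
            labels, _, _ = score_night(series, cfg)
            if prev is not None:
                assert np.all(prev <= labels.asleep)  # sleep set non-decreasing
            prev = labels.asleep

    def test_determinism(self, config):
        series = deterministic_night()
        a = score_night(series, config)
        b = score_night(series, config)
        assert np.array_equal(a[0].asleep, b[0].asleep)
        assert a[1:] == b[1:]
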