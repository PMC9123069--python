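"""Alarm engine: streak rules, adaptive thresholds, slope strategy."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wardalarm import (
    AlarmConfig,
    AnnunciationDelay,
    ConfigurationError,
    DaytimeElevation,
    Direction,
    IndividualizedThresholds,
    NighttimeReduction,
    PatientState,
    PostopElevation,
    SlopeTrend,
    Vital,
    compute_individual_thresholds,
    effective_thresholds,
    run_baseline_alarms,
    run_slope_alarms,
    run_strategy,
    threshold_arrays,
)
from wardalarm.engine import _streak_alarms

from helpers import T0, STEP, make_trace, oracle_streak_alarms


def hr_trace(values, valid=None, **kwargs):
    return make_trace(hr=values, hr_valid=valid, **kwargs)


class TestBaselineStreaks:
    def test_all_in_range_no_alarms(self):
        trace = make_trace(hr=70.0, rr=14.0, temp=36.8, n=720)  # 24 h
        assert run_baseline_alarms(trace) == []

    def test_exactly_seven_abnormal_triggers_once_with_12_min_delay(self):
        hr = np.full(100, 70.0)
        hr[20:27] = 130.0
        alarms = run_baseline_alarms(hr_trace(hr))
        assert len(alarms) == 1
        a = alarms[0]
        assert (a.vital, a.direction) == (Vital.HR, Direction.HIGH)
        assert a.window_start == T0 + 20 * STEP
        assert a.trigger_time == T0 + 26 * STEP
        assert a.trigger_time - a.window_start == pd.Timedelta(minutes=12)

    def test_six_abnormal_samples_do_not_alarm(self):
        hr = np.full(100, 70.0)
        hr[20:26] = 130.0
        assert run_baseline_alarms(hr_trace(hr)) == []

    def test_normal_range_boundaries_are_inclusive(self):
        assert run_baseline_alarms(hr_trace(np.full(50, 120.0))) == []
        assert len(run_baseline_alarms(hr_trace(np.full(50, 121.0)))) >= 1
        assert run_baseline_alarms(hr_trace(np.full(50, 40.0))) == []
        assert len(run_baseline_alarms(hr_trace(np.full(50, 39.0)))) >= 1
        assert run_baseline_alarms(make_trace(temp=np.full(50, 38.0), n=50)) == []
        assert len(run_baseline_alarms(make_trace(temp=np.full(50, 38.1), n=50))) >= 1

    def test_temperature_has_no_lower_limit(self):
        assert run_baseline_alarms(make_trace(temp=np.full(100, 31.0), n=100)) == []

    def test_rearm_requires_five_normal_samples(self):
        hr = np.full(60, 70.0)
        hr[10:17] = 130.0  # first alarm
        hr[17:21] = 70.0  # only 4 normals: not re-armed
        hr[21:28] = 130.0  # suppressed
        alarms = run_baseline_alarms(hr_trace(hr))
        assert len(alarms) == 1

        hr2 = np.full(60, 70.0)
        hr2[10:17] = 130.0
        hr2[17:22] = 70.0  # 5 normals: re-armed
        hr2[22:29] = 130.0
        assert len(run_baseline_alarms(hr_trace(hr2))) == 2

    def test_missing_samples_lengthen_but_do_not_cancel_the_delay(self):
        hr = np.full(60, 130.0)
        valid = np.ones(60, dtype=bool)
        valid[3:10] = False  # gap inside the abnormal streak
        alarms = run_baseline_alarms(hr_trace(hr, valid=valid))
        assert len(alarms) >= 1
        # trigger at the 7th usable abnormal sample: indices 0,1,2,10,11,12,13
        assert alarms[0].trigger_time == T0 + 13 * STEP
        assert alarms[0].window_start == T0

    def test_sustained_abnormality_yields_single_alarm(self):
        alarms = run_baseline_alarms(hr_trace(np.full(720, 130.0)))
        assert len(alarms) == 1

    def test_unsorted_grid_rejected(self):
        trace = make_trace(hr=70.0, n=20)
        trace.samples = trace.samples.iloc[::-1]
        from wardalarm import TraceError

        with pytest.raises(TraceError):
            run_baseline_alarms(trace)


class TestStreakOracleEquivalence:
    """Streaming machine vs maximal-run enumeration of the literal rules."""

    @pytest.mark.parametrize("n_abnormal,n_rearm", [(7, 5), (3, 2), (1, 0), (5, 0)])
    def test_random_traces_match_oracle(self, n_abnormal, n_rearm):
        rng = np.random.default_rng(20240301 + n_abnormal * 10 + n_rearm)
        config = AlarmConfig(n_abnormal=n_abnormal, n_rearm=n_rearm)
        for _ in range(60):
            n = int(rng.integers(20, 1000))
            # random walk hovering around the upper and lower HR limits
            hr = np.clip(80.0 + np.cumsum(rng.normal(0, 18, n)), 1, 299)
            valid = rng.random(n) > 0.15
            trace = hr_trace(hr, valid=valid)
            got = [
                (a.window_start, a.trigger_time, a.direction)
                for a in run_baseline_alarms(trace, config)
                if a.vital is Vital.HR
            ]
            expected = []
            for direction in (Direction.HIGH, Direction.LOW):
                for ws, tt in oracle_streak_alarms(
                    hr, valid, 40.0, 120.0, direction, n_abnormal, n_rearm
                ):
                    expected.append((trace.times[ws], trace.times[tt], direction))
            assert sorted(got) == sorted(expected)

    @given(
        syms=st.lists(st.sampled_from("ANOX"), min_size=1, max_size=120),
        n_abnormal=st.integers(1, 8),
        n_rearm=st.integers(0, 6),
    )
    @settings(max_examples=300, deadline=None)
    def test_symbolic_sequences_match_oracle(self, syms, n_abnormal, n_rearm):
        """'A' abnormal-high, 'N' in range, 'O' abnormal-low, 'X' unusable."""
        value = {"A": 130.0, "N": 70.0, "O": 30.0, "X": 70.0}
        hr = np.array([value[s] for s in syms])
        usable = np.array([s != "X" for s in syms])
        times = pd.date_range(T0, periods=len(syms), freq=STEP)
        abnormal = usable & (hr > 120.0)
        in_range = usable & (hr <= 120.0) & (hr >= 40.0)
        got = _streak_alarms(times, abnormal, in_range, usable, n_abnormal, n_rearm)
        expected = [
            (times[ws], times[tt])
            for ws, tt in oracle_streak_alarms(
                hr, usable, 40.0, 120.0, Direction.HIGH, n_abnormal, n_rearm
            )
        ]
        assert got == expected


class TestMonotonicity:
    def _random_trace(self, seed):
        rng = np.random.default_rng(seed)
        hr = np.clip(90.0 + np.cumsum(rng.normal(0, 10, 600)), 1, 299)
        return hr_trace(hr, valid=rng.random(600) > 0.1)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_raising_upper_threshold_never_adds_alarms(self, seed):
        # Strict threshold monotonicity is a theorem of the pure annunciation
        # mechanism (re-arm disabled): shrinking the abnormal set pointwise
        # can only shorten or split abnormal runs, and sum(floor(len/n))
        # decreases under both. Re-arm suppression breaks strictness (see
        # test_rearm_can_invert_threshold_monotonicity).
        from wardalarm import Limits, ThresholdSet

        trace = self._random_trace(seed)
        counts = []
        for upper in (100.0, 110.0, 120.0, 140.0, 170.0):
            cfg = AlarmConfig(
                thresholds=ThresholdSet(hr=Limits(40.0, upper)), n_rearm=0
            )
            counts.append(len(run_baseline_alarms(trace, cfg)))
        assert counts == sorted(counts, reverse=True)

    def test_rearm_can_invert_threshold_monotonicity(self):
        # With re-arm active, raising the upper threshold can split one long
        # abnormal streak (one alarm, then suppression) into two qualifying
        # streaks separated by enough normal samples to re-arm (two alarms).
        from wardalarm import Limits, ThresholdSet

        hr = np.concatenate(
            [np.full(7, 130.0), np.full(5, 115.0), np.full(7, 130.0), np.full(10, 70.0)]
        )
        trace = hr_trace(hr)
        counts = {}
        for upper in (110.0, 120.0):
            cfg = AlarmConfig(thresholds=ThresholdSet(hr=Limits(40.0, upper)))
            counts[upper] = len(run_baseline_alarms(trace, cfg))
        assert counts == {110.0: 1, 120.0: 2}

    @pytest.mark.parametrize("seed", [10, 11, 12, 13, 14])
    def test_longer_annunciation_delay_never_adds_alarms(self, seed):
        trace = self._random_trace(seed)
        counts = [
            len(run_baseline_alarms(trace, AlarmConfig(n_abnormal=k)))
            for k in (1, 3, 7, 12, 17, 22)
        ]
        assert counts == sorted(counts, reverse=True)

    @pytest.mark.parametrize("seed", [20, 21, 22])
    def test_rearm_invariant_on_generated_logs(self, seed):
        trace = self._random_trace(seed)
        config = AlarmConfig()
        alarms = [a for a in run_baseline_alarms(trace, config)
                  if a.direction is Direction.HIGH]
        hr = trace.values(Vital.HR)
        usable = trace.valid(Vital.HR)
        for prev, nxt in zip(alarms, alarms[1:]):
            i0 = trace.times.get_loc(prev.trigger_time)
            i1 = trace.times.get_loc(nxt.window_start)
            run = best = 0
            for i in range(i0 + 1, i1):
                if not usable[i]:
                    continue
                if 40.0 <= hr[i] <= 120.0:
                    run += 1
                    best = max(best, run)
                else:
                    run = 0
            assert best >= config.n_rearm


class TestEffectiveThresholds:
    def test_no_strategies_returns_defaults(self):
        cfg = AlarmConfig()
        state = PatientState(surgery_end=T0)
        ts = effective_thresholds(cfg, state, T0 + pd.Timedelta(hours=5))
        assert (ts.hr.lower, ts.hr.upper) == (40.0, 120.0)
        assert (ts.rr.lower, ts.rr.upper) == (8.0, 24.0)
        assert (ts.temp.lower, ts.temp.upper) == (None, 38.0)

    def test_postop_elevation_active_then_expired(self):
        cfg = AlarmConfig(strategies=(PostopElevation(
            {Vital.HR: 0.05, Vital.RR: 0.05, Vital.TEMP: 0.01}),))
        state = PatientState(surgery_end=T0)
        ts = effective_thresholds(cfg, state, T0 + pd.Timedelta(hours=12))
        assert ts.hr.upper == pytest.approx(126.0)
        assert ts.rr.upper == pytest.approx(25.2)
        assert ts.temp.upper == pytest.approx(38.38)
        ts5d = effective_thresholds(cfg, state, T0 + pd.Timedelta(days=5))
        assert (ts5d.hr.upper, ts5d.rr.upper, ts5d.temp.upper) == (120.0, 24.0, 38.0)

    def test_nighttime_reduction_only_at_night(self):
        cfg = AlarmConfig(strategies=(NighttimeReduction({Vital.HR: 0.10}),))
        state = PatientState(surgery_end=T0)
        at_night = effective_thresholds(cfg, state, T0 + pd.Timedelta(hours=3))
        at_noon = effective_thresholds(cfg, state, T0 + pd.Timedelta(hours=12))
        assert at_night.hr.lower == pytest.approx(36.0)
        assert at_noon.hr.lower == 40.0

    def test_daytime_elevation_only_during_day(self):
        cfg = AlarmConfig(strategies=(DaytimeElevation({Vital.HR: 0.10}),))
        state = PatientState(surgery_end=T0)
        day = effective_thresholds(cfg, state, T0 + pd.Timedelta(hours=12))
        night = effective_thresholds(cfg, state, T0 + pd.Timedelta(hours=23))
        assert day.hr.upper == pytest.approx(132.0)
        assert night.hr.upper == 120.0

    def test_modifiers_compose_multiplicatively(self):
        cfg = AlarmConfig(strategies=(
            PostopElevation({Vital.HR: 0.05}),
            DaytimeElevation({Vital.HR: 0.10}),
        ))
        state = PatientState(surgery_end=T0)
        ts = effective_thresholds(cfg, state, T0 + pd.Timedelta(hours=12))
        assert ts.hr.upper == pytest.approx(120.0 * 1.05 * 1.10)


class TestIndividualizedThresholds:
    def test_constant_signal_collapses_the_normal_range(self):
        trace = make_trace(hr=70.0, n=800)
        ts = compute_individual_thresholds(trace, 1.0, 99.0)
        assert ts.hr.lower == 70.0
        assert ts.hr.upper == 70.0

    def test_percentiles_match_hand_computed_order_statistics(self):
        hr = np.zeros(800)
        hr[:100] = np.arange(1, 101)  # first 100 samples: 1..100
        valid = np.zeros(800, dtype=bool)
        valid[:100] = True
        trace = make_trace(hr=np.where(valid, hr, 70.0), hr_valid=valid, n=800)
        ts = compute_individual_thresholds(trace, 1.0, 99.0)
        # linear interpolation between order statistics, computed by hand:
        # rank 0.01*(100-1) = 0.99 -> 1 + 0.99; rank 98.01 -> 99 + 0.01
        assert ts.hr.lower == pytest.approx(1.99)
        assert ts.hr.upper == pytest.approx(99.01)

    def test_temperature_keeps_no_lower_limit(self):
        trace = make_trace(n=800)
        ts = compute_individual_thresholds(trace, 1.0, 99.0)
        assert ts.temp.lower is None
        assert ts.temp.upper is not None

    def test_insufficient_samples_fall_back_to_defaults(self, caplog):
        valid = np.zeros(800, dtype=bool)
        valid[:10] = True
        trace = make_trace(hr=90.0, hr_valid=valid, n=800)
        import logging

        with caplog.at_level(logging.WARNING):
            ts = compute_individual_thresholds(trace, 1.0, 99.0)
        assert (ts.hr.lower, ts.hr.upper) == (40.0, 120.0)
        assert any("default" in r.message for r in caplog.records)

    def test_individualized_thresholds_apply_only_after_24h(self):
        # tight baseline for 24 h, then a level inside the default range but
        # outside the individualized one
        hr = np.concatenate([np.full(720, 70.0), np.full(720, 100.0)])
        trace = hr_trace(hr)
        cfg = AlarmConfig(strategies=(IndividualizedThresholds(1.0, 99.0),))
        alarms = run_strategy(trace, cfg)
        assert alarms, "excursion above the individualized upper limit must alarm"
        assert min(a.trigger_time for a in alarms) >= T0 + pd.Timedelta(hours=24)


class TestSlopeStrategy:
    def test_constant_trace_never_alarms(self):
        trace = make_trace(hr=90.0, n=900)
        assert run_slope_alarms(trace, SlopeTrend(pd.Timedelta(hours=4))) == []

    def test_20bpm_over_4h_ramp_alarms_and_10bpm_does_not(self):
        n = 24 * 30
        ramp_fast = 70.0 + (20.0 / 120.0) * np.arange(n)  # 20 bpm per 4 h
        ramp_slow = 70.0 + (10.0 / 120.0) * np.arange(n)
        fast = make_trace(hr=np.clip(ramp_fast, 1, 299), n=n)
        slow = make_trace(hr=ramp_slow, n=n)
        params = SlopeTrend(pd.Timedelta(hours=4))
        alarms = run_slope_alarms(fast, params)
        assert alarms and all(a.direction is Direction.HIGH for a in alarms)
        assert run_slope_alarms(slow, params) == []

    def test_absolute_level_is_ignored(self):
        # constant at a level far above the static threshold: no slope alarm
        trace = make_trace(hr=140.0, n=900)
        assert run_slope_alarms(trace, SlopeTrend(pd.Timedelta(hours=4))) == []

    def test_downward_trend_fires_low_alarms(self):
        n = 720
        hr = np.clip(120.0 - (20.0 / 120.0) * np.arange(n), 1, 299)
        alarms = run_slope_alarms(make_trace(hr=hr, n=n), SlopeTrend(pd.Timedelta(hours=4)))
        assert alarms and all(a.direction is Direction.LOW for a in alarms)

    def test_zero_limits_fire_on_any_persistent_trend(self):
        n = 720
        hr = 70.0 + (5.0 / 120.0) * np.arange(n)
        params = SlopeTrend(pd.Timedelta(hours=4),
                            {Vital.HR: 0.0, Vital.RR: 0.0, Vital.TEMP: 0.0})
        assert run_slope_alarms(make_trace(hr=hr, n=n), params)

    def test_huge_limits_never_fire(self):
        n = 720
        hr = 70.0 + (40.0 / 120.0) * np.arange(n)
        params = SlopeTrend(pd.Timedelta(hours=4),
                            {Vital.HR: 1e9, Vital.RR: 1e9, Vital.TEMP: 1e9})
        assert run_slope_alarms(make_trace(hr=np.clip(hr, 1, 299), n=n), params) == []

    def test_sparse_windows_are_skipped(self, caplog):
        import logging

        valid = np.zeros(900, dtype=bool)
        valid[::4] = True  # 25% coverage everywhere
        trace = make_trace(hr=70.0, hr_valid=valid, rr_valid=valid, temp_valid=valid, n=900)
        with caplog.at_level(logging.WARNING):
            alarms = run_slope_alarms(trace, SlopeTrend(pd.Timedelta(hours=4)))
        assert alarms == []
        assert any("coverage" in r.message for r in caplog.records)

    def test_short_window_rejected(self):
        trace = make_trace(hr=70.0, n=900)
        with pytest.raises(ConfigurationError):
            run_slope_alarms(trace, SlopeTrend(pd.Timedelta(minutes=30)))


class TestStrategyDispatch:
    def test_empty_strategy_set_equals_baseline(self, small_cohort):
        traces, _ = small_cohort
        for trace in traces[:4]:
            base = run_baseline_alarms(trace)
            got = run_strategy(trace, AlarmConfig())
            assert [
                (a.vital, a.direction, a.trigger_time, a.window_start) for a in got
            ] == [(a.vital, a.direction, a.trigger_time, a.window_start) for a in base]

    @pytest.mark.parametrize(
        "strategy",
        [
            PostopElevation({Vital.HR: 0.0, Vital.RR: 0.0, Vital.TEMP: 0.0}),
            DaytimeElevation({Vital.HR: 0.0, Vital.RR: 0.0}),
            NighttimeReduction({Vital.HR: 0.0, Vital.RR: 0.0}),
            AnnunciationDelay(7),
        ],
        ids=["II-zero", "IV-zero", "V-zero", "III-default"],
    )
    def test_neutral_strategy_settings_equal_baseline(self, small_cohort, strategy):
        traces, _ = small_cohort
        for trace in traces[:4]:
            base = run_baseline_alarms(trace)
            got = run_strategy(trace, AlarmConfig(strategies=(strategy,)))
            assert [
                (a.vital, a.direction, a.trigger_time, a.window_start) for a in got
            ] == [(a.vital, a.direction, a.trigger_time, a.window_start) for a in base]

    def test_slope_strategy_cannot_be_combined(self):
        with pytest.raises(ConfigurationError):
            AlarmConfig(strategies=(SlopeTrend(), PostopElevation()))

    def test_strategy_iii_sets_the_delay(self):
        hr = np.full(100, 70.0)
        hr[20:31] = 130.0  # 11 successive abnormal samples
        trace = hr_trace(hr)
        assert run_baseline_alarms(trace)  # 7-sample rule fires
        assert run_strategy(trace, AlarmConfig(strategies=(AnnunciationDelay(12),))) == []
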