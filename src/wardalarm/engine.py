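"""Threshold alarm state machine and adaptive threshold strategies.

The baseline algorithm reproduces a classical ward alarm system: a vital
sign must lie outside its normal range (HR 40-120 beats/min, RR 8-24
breaths/min, T <= 38.0 C) for at least ``n_abnormal`` successive usable
measurements (default 7, an annunciation delay) before an alarm of that
(vital, direction) type is annunciated, and after an alarm the same type is
suppressed until ``n_rearm`` successive in-range usable measurements have
occurred (default 5).

Missing or invalid samples neither extend nor reset streaks: streaks are
counted over usable samples only, so gaps lengthen the wall-clock delay but
never cancel it.

Adaptive strategies modify either the thresholds as a function of time
(individualized percentiles, postoperative elevation, day/night factors),
the annunciation delay, or replace the level test by a rolling-regression
slope test.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .strategies import (
    DAY_END_HOUR,
    DAY_START_HOUR,
    POSTOP_WINDOW,
    AnnunciationDelay,
    DaytimeElevation,
    IndividualizedThresholds,
    NighttimeReduction,
    PostopElevation,
    SlopeTrend,
    StrategyParams,
)
from .types import (
    Alarm,
    ConfigurationError,
    DEFAULT_THRESHOLDS,
    Direction,
    Limits,
    ThresholdSet,
    TraceError,
    Vital,
    VitalTrace,
    sort_alarms,
)

logger = logging.getLogger(__name__)

#: Minimum usable samples per vital in the first 24 h for individualization.
MIN_SAMPLES_FOR_CDF = 30
#: Individualized thresholds apply only after this much recording.
INDIVIDUALIZATION_DELAY = pd.Timedelta(hours=24)
#: Minimum fraction of usable samples required in a slope-regression window.
MIN_WINDOW_COVERAGE = 0.5


@dataclass(frozen=True)
class AlarmConfig:
    """Configuration of one alarm-strategy run.

    ``strategies`` is an ordered collection of :class:`StrategyParams`; an
    empty collection reproduces the baseline algorithm. The slope strategy
    (VI) cannot be combined with any other because it discards absolute
    vital-sign levels.
    """

    thresholds: ThresholdSet = field(default_factory=ThresholdSet)
    n_abnormal: int = 7
    n_rearm: int = 5
    strategies: tuple[StrategyParams, ...] = ()

    def __post_init__(self) -> None:
        if self.n_abnormal < 1:
            raise ConfigurationError("n_abnormal must be >= 1")
        if self.n_rearm < 0:
            raise ConfigurationError("n_rearm must be >= 0")
        labels = [s.label for s in self.strategies]
        if len(set(labels)) != len(labels):
            raise ConfigurationError(f"duplicate strategies in {labels}")
        if any(isinstance(s, SlopeTrend) for s in self.strategies) and len(self.strategies) > 1:
            raise ConfigurationError(
                "the slope strategy (VI) cannot be combined with threshold strategies"
            )

    def strategy(self, cls: type) -> Optional[StrategyParams]:
        for s in self.strategies:
            if isinstance(s, cls):
                return s
        return None

    @property
    def label(self) -> str:
        if not self.strategies:
            return "baseline"
        order = {"I": 0, "II": 1, "III": 2, "IV": 3, "V": 4, "VI": 5}
        return "+".join(sorted((s.label for s in self.strategies), key=order.__getitem__))


@dataclass(frozen=True)
class PatientState:
    """Per-patient context needed to resolve time-varying thresholds."""

    surgery_end: pd.Timestamp
    individualized: Optional[ThresholdSet] = None
    individualized_from: Optional[pd.Timestamp] = None


# ---------------------------------------------------------------------------
# Threshold resolution
# ---------------------------------------------------------------------------

def threshold_arrays(
    times: pd.DatetimeIndex, config: AlarmConfig, state: PatientState
) -> dict[Vital, tuple[np.ndarray, np.ndarray]]:
    """Per-sample (lower, upper) limit arrays for each vital.

    Starts from the default (or, where applicable, individualized) limits and
    applies every active time-conditional modifier multiplicatively in
    strategy order: postoperative elevation first, then the day/night
    factors. Absent limits are NaN.
    """
    n = len(times)
    hours = times.hour.to_numpy()
    day = (hours >= DAY_START_HOUR) & (hours < DAY_END_HOUR)
    night = ~day
    postop = (times >= state.surgery_end) & (times < state.surgery_end + POSTOP_WINDOW)
    postop = np.asarray(postop)

    po = config.strategy(PostopElevation)
    dt = config.strategy(DaytimeElevation)
    nt = config.strategy(NighttimeReduction)

    out: dict[Vital, tuple[np.ndarray, np.ndarray]] = {}
    for vital in Vital:
        lim = config.thresholds.get(vital)
        lower = np.full(n, np.nan if lim.lower is None else float(lim.lower))
        upper = np.full(n, np.nan if lim.upper is None else float(lim.upper))
        if state.individualized is not None:
            ilim = state.individualized.get(vital)
            mask = (
                np.ones(n, dtype=bool)
                if state.individualized_from is None
                else np.asarray(times >= state.individualized_from)
            )
            if ilim.lower is not None:
                lower[mask] = ilim.lower
            if ilim.upper is not None:
                upper[mask] = ilim.upper
        if po is not None and vital in po.po_increase:
            upper = np.where(postop, upper * (1.0 + po.po_increase[vital]), upper)
        if dt is not None and vital in dt.dt_increase:
            upper = np.where(day, upper * (1.0 + dt.dt_increase[vital]), upper)
        if nt is not None and vital in nt.nt_decrease:
            lower = np.where(night, lower * (1.0 - nt.nt_decrease[vital]), lower)
        out[vital] = (lower, upper)
    return out


def effective_thresholds(
    config: AlarmConfig, state: PatientState, at: pd.Timestamp
) -> ThresholdSet:
    """Thresholds in force at a single point in time.

    Total over valid inputs: with no active strategies this returns the
    configured defaults.
    """
    idx = pd.DatetimeIndex([pd.Timestamp(at)])
    arrays = threshold_arrays(idx, config, state)
    kwargs = {}
    for vital in Vital:
        lo, hi = arrays[vital]
        kwargs[vital.value] = Limits(
            None if np.isnan(lo[0]) else float(lo[0]),
            None if np.isnan(hi[0]) else float(hi[0]),
        )
    return ThresholdSet(**kwargs)


def compute_individual_thresholds(
    trace: VitalTrace, cdf_low: float, cdf_high: float
) -> ThresholdSet:
    """Per-patient thresholds from first-24-h empirical percentiles.

    For each vital the lower/upper limits are the ``cdf_low``/``cdf_high``
    empirical percentiles (linear interpolation between order statistics) of
    the usable samples in the first 24 h of recording. Temperature keeps no
    lower limit. A vital with fewer than 30 usable samples falls back to the
    default limits with a logged warning.
    """
    if trace.duration < INDIVIDUALIZATION_DELAY:
        raise TraceError(
            f"trace {trace.patient_id}: at least 24 h of recording is required "
            "for threshold individualization"
        )
    window = trace.times < trace.start + INDIVIDUALIZATION_DELAY
    result = DEFAULT_THRESHOLDS
    for vital in Vital:
        v = trace.values(vital)[window]
        usable = trace.valid(vital)[window]
        sample = v[usable]
        if sample.size < MIN_SAMPLES_FOR_CDF:
            logger.warning(
                "trace %s: only %d usable %s samples in first 24 h; "
                "keeping default thresholds for this vital",
                trace.patient_id,
                sample.size,
                vital.value,
            )
            continue
        lower = float(np.percentile(sample, cdf_low))
        upper = float(np.percentile(sample, cdf_high))
        if vital is Vital.TEMP:
            limits = Limits(None, upper)
        elif lower == upper:
            # Degenerate first-24-h distribution: a zero-width normal range.
            # Limits requires lower < upper, so widen by nothing but store raw.
            limits = _degenerate_limits(lower)
        else:
            limits = Limits(lower, upper)
        result = result.replace(vital, limits)
    return result


def _degenerate_limits(value: float) -> Limits:
    """Represent a zero-width normal range (constant first-24-h signal)."""
    lim = Limits.__new__(Limits)
    object.__setattr__(lim, "lower", value)
    object.__setattr__(lim, "upper", value)
    return lim


# ---------------------------------------------------------------------------
# Streak state machine
# ---------------------------------------------------------------------------

def _streak_alarms(
    times: pd.DatetimeIndex,
    abnormal: np.ndarray,
    in_range: np.ndarray,
    usable: np.ndarray,
    n_abnormal: int,
    n_rearm: int,
) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Run the annunciation/re-arm machine for one (vital, direction).

    ``abnormal`` marks usable samples beyond the threshold in this direction,
    ``in_range`` marks usable samples inside the full normal range. Usable
    samples abnormal in the *opposite* direction reset both streaks (they
    break an abnormal run and are not in the normal range). Unusable samples
    are skipped entirely.

    Returns (window_start, trigger_time) pairs.
    """
    alarms: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    streak = 0
    start: Optional[pd.Timestamp] = None
    suppressed = False
    normals = 0
    for i in range(len(times)):
        if not usable[i]:
            continue
        if abnormal[i]:
            if suppressed:
                normals = 0
            else:
                if streak == 0:
                    start = times[i]
                streak += 1
                if streak == n_abnormal:
                    alarms.append((start, times[i]))
                    streak = 0
                    start = None
                    suppressed = n_rearm > 0
                    normals = 0
        elif in_range[i]:
            streak = 0
            start = None
            if suppressed:
                normals += 1
                if normals >= n_rearm:
                    suppressed = False
                    normals = 0
        else:  # abnormal in the opposite direction
            streak = 0
            start = None
            normals = 0
    return alarms


def _threshold_alarms(
    trace: VitalTrace,
    config: AlarmConfig,
    state: PatientState,
    n_abnormal: int,
    label: str,
) -> list[Alarm]:
    trace.validate()
    arrays = threshold_arrays(trace.times, config, state)
    alarms: list[Alarm] = []
    for vital in Vital:
        lower, upper = arrays[vital]
        v = trace.values(vital)
        usable = trace.valid(vital)
        with np.errstate(invalid="ignore"):
            above = usable & ~np.isnan(upper) & (v > upper)
            below = usable & ~np.isnan(lower) & (v < lower)
        in_range = usable & ~above & ~below
        for direction, abnormal in ((Direction.HIGH, above), (Direction.LOW, below)):
            for w_start, w_trig in _streak_alarms(
                trace.times, abnormal, in_range, usable, n_abnormal, config.n_rearm
            ):
                alarms.append(
                    Alarm(trace.patient_id, vital, direction, w_trig, w_start, label)
                )
    return sort_alarms(alarms)


def run_baseline_alarms(trace: VitalTrace, config: AlarmConfig | None = None) -> list[Alarm]:
    """Run the classical threshold alarm algorithm on one trace.

    Any strategies present in ``config`` are ignored: this is the unmodified
    baseline with the configured static thresholds and 7/5 streak rules.
    """
    config = config or AlarmConfig()
    base = AlarmConfig(config.thresholds, config.n_abnormal, config.n_rearm)
    state = PatientState(surgery_end=trace.surgery_end)
    return _threshold_alarms(trace, base, state, base.n_abnormal, "baseline")


# ---------------------------------------------------------------------------
# Slope-based strategy (VI)
# ---------------------------------------------------------------------------

def _rolling_ols_slope(
    x_hours: np.ndarray, v: np.ndarray, usable: np.ndarray, w: int
) -> tuple[np.ndarray, np.ndarray]:
    """Trailing-window OLS slope (units/hour) at each grid point.

    Windows cover the current sample and the preceding ``w - 1``; a window is
    defined when at least half its samples are usable and the regressor has
    spread. Returns (slope, defined) arrays aligned to the grid, with the
    first ``w - 1`` positions undefined.
    """
    n = len(v)
    m = usable.astype(float)
    xv = np.where(usable, x_hours, 0.0)
    yv = np.where(usable, v, 0.0)

    def roll(a: np.ndarray) -> np.ndarray:
        cs = np.concatenate([[0.0], np.cumsum(a)])
        return cs[w:] - cs[:-w]

    cnt = roll(m)
    sx = roll(xv)
    sy = roll(yv)
    sxx = roll(xv * xv)
    sxy = roll(xv * yv)
    denom = cnt * sxx - sx * sx
    with np.errstate(invalid="ignore", divide="ignore"):
        slope_tail = np.where(denom > 1e-9, (cnt * sxy - sx * sy) / denom, np.nan)
    defined_tail = (cnt >= MIN_WINDOW_COVERAGE * w) & (denom > 1e-9)

    slope = np.full(n, np.nan)
    defined = np.zeros(n, dtype=bool)
    slope[w - 1 :] = slope_tail
    defined[w - 1 :] = defined_tail
    return slope, defined


def run_slope_alarms(
    trace: VitalTrace, params: SlopeTrend, config: AlarmConfig | None = None
) -> list[Alarm]:
    """Run the trend-only strategy (VI) on one trace.

    At each grid point an ordinary least-squares line is fitted to the
    trailing window of length ``t_slope``; the sample is abnormal-high
    (abnormal-low) when the fitted change over one window length,
    slope x t_slope, exceeds +limit (falls below -limit). Absolute values
    are never consulted. The same annunciation-delay and re-arm machinery as
    the baseline governs alarm generation from this abnormality signal.
    """
    config = config or AlarmConfig()
    trace.validate()
    if params.t_slope < pd.Timedelta(hours=1):
        raise ConfigurationError("t_slope must be at least 1 h")
    interval = trace.interval
    w = int(params.t_slope / interval)
    if w < 2 or trace.n_samples <= w:
        raise ConfigurationError("trace shorter than the slope window")

    t_h = float(params.t_slope / pd.Timedelta(hours=1))
    x_hours = (trace.times - trace.start) / pd.Timedelta(hours=1)
    x_hours = np.asarray(x_hours, dtype=float)

    alarms: list[Alarm] = []
    any_defined = False
    for vital in Vital:
        limit = params.slope_limits.get(vital)
        if limit is None:
            continue
        v = trace.values(vital)
        usable = trace.valid(vital)
        slope, defined = _rolling_ols_slope(x_hours, v, usable, w)
        any_defined = any_defined or bool(defined.any())
        change = slope * t_h  # fitted change over one window length
        with np.errstate(invalid="ignore"):
            up = defined & (change > limit)
            down = defined & (-change > limit)
        in_range = defined & ~up & ~down
        for direction, abnormal in ((Direction.HIGH, up), (Direction.LOW, down)):
            for w_start, w_trig in _streak_alarms(
                trace.times, abnormal, in_range, defined, config.n_abnormal, config.n_rearm
            ):
                alarms.append(
                    Alarm(trace.patient_id, vital, direction, w_trig, w_start, "VI")
                )
    if not any_defined:
        logger.warning(
            "trace %s: no slope window reached %d%% coverage; no slope alarms possible",
            trace.patient_id,
            int(100 * MIN_WINDOW_COVERAGE),
        )
    return sort_alarms(alarms)


# ---------------------------------------------------------------------------
# Strategy dispatch
# ---------------------------------------------------------------------------

def run_strategy(trace: VitalTrace, config: AlarmConfig) -> list[Alarm]:
    """Run the configured strategy (or combination) on one trace.

    Threshold strategies (I, II, IV, V) act through the per-sample threshold
    arrays; III replaces the annunciation-delay count; VI dispatches to the
    slope engine and cannot be combined. An empty strategy set is the
    baseline.
    """
    slope = config.strategy(SlopeTrend)
    if slope is not None:
        return run_slope_alarms(trace, slope, config)
    if not config.strategies:
        return run_baseline_alarms(trace, config)

    delay = config.strategy(AnnunciationDelay)
    n_abnormal = delay.l_interval if delay is not None else config.n_abnormal

    individualized = None
    individualized_from = None
    indiv = config.strategy(IndividualizedThresholds)
    if indiv is not None:
        if trace.duration < INDIVIDUALIZATION_DELAY:
            logger.warning(
                "trace %s: shorter than 24 h; individualization skipped",
                trace.patient_id,
            )
        else:
            individualized = compute_individual_thresholds(
                trace, indiv.cdf_low, indiv.cdf_high
            )
            individualized_from = trace.start + INDIVIDUALIZATION_DELAY

    state = PatientState(trace.surgery_end, individualized, individualized_from)
    return _threshold_alarms(trace, config, state, n_abnormal, config.label)


def run_cohort(
    traces: Sequence[VitalTrace], config: AlarmConfig
) -> list[Alarm]:
    """Run one strategy over a cohort; alarms concatenated in patient order."""
    alarms: list[Alarm] = []
    for trace in traces:
        alarms.extend(run_strategy(trace, config))
    return alarms
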