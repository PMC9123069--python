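"""Core domain types shared by the cohort simulator, alarm engine and evaluation layers.

The data model mirrors what a wearable ward-monitoring system produces:
per-patient vital-sign traces (heart rate, respiratory rate, axillary
temperature) on a regular 2-minute grid, alarm annunciations, and
retrospectively annotated adverse events.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: Nominal sampling interval of the monitoring system.
SAMPLING_INTERVAL = pd.Timedelta(minutes=2)


class Vital(str, enum.Enum):
    """Monitored vital sign channels."""

    HR = "hr"  # heart rate, beats/min
    RR = "rr"  # respiratory rate, breaths/min
    TEMP = "temp"  # axillary temperature, degrees C


class Direction(str, enum.Enum):
    """Side of the normal range an abnormality (or alarm) lies on."""

    HIGH = "high"
    LOW = "low"


class Severity(str, enum.Enum):
    """Clavien-Dindo surgical-complication severity grade (only I-III occur here)."""

    I = "I"
    II = "II"
    III = "III"


# Hard physiological plausibility bounds for present samples (open intervals).
PHYSIOLOGICAL_BOUNDS: dict[Vital, tuple[float, float]] = {
    Vital.HR: (0.0, 300.0),
    Vital.RR: (0.0, 80.0),
    Vital.TEMP: (30.0, 43.0),
}

VALUE_COLUMNS = {Vital.HR: "hr", Vital.RR: "rr", Vital.TEMP: "temp"}
VALID_COLUMNS = {Vital.HR: "hr_valid", Vital.RR: "rr_valid", Vital.TEMP: "temp_valid"}
TRACE_COLUMNS = ["hr", "rr", "temp", "hr_valid", "rr_valid", "temp_valid"]


class WardAlarmError(Exception):
    """Base class for package errors."""


class ConfigurationError(WardAlarmError):
    """Invalid configuration (spec fields, strategy parameters, combinations)."""


class DataError(WardAlarmError):
    """Invalid input data (traces, annotations, files)."""


class TraceError(DataError):
    """Vital-sign trace violates its structural invariants."""


class AnnotationError(DataError):
    """Adverse-event annotation inconsistent with the trace it refers to."""


class ParseError(DataError):
    """Malformed file content."""


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (display convention for reports)."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return x
    factor = 10.0**ndigits
    r = math.floor(abs(x) * factor + 0.5) / factor
    r = math.copysign(r, x)
    return r if ndigits > 0 else float(int(r))


@dataclass(frozen=True)
class Limits:
    """Lower/upper alarm limits for one vital; either side may be absent."""

    lower: Optional[float]
    upper: Optional[float]

    def __post_init__(self) -> None:
        if self.lower is not None and self.upper is not None and not self.lower < self.upper:
            raise ConfigurationError(
                f"lower limit {self.lower} must be below upper limit {self.upper}"
            )


@dataclass(frozen=True)
class ThresholdSet:
    """Per-vital alarm limits.

    The factory defaults reproduce the normal ranges of the original ward
    alarm system: HR 40-120 beats/min, RR 8-24 breaths/min, T <= 38.0 C
    (temperature has no lower limit). Values exactly on a limit count as
    normal; abnormal is strictly outside.
    """

    hr: Limits = field(default_factory=lambda: Limits(40.0, 120.0))
    rr: Limits = field(default_factory=lambda: Limits(8.0, 24.0))
    temp: Limits = field(default_factory=lambda: Limits(None, 38.0))

    def get(self, vital: Vital) -> Limits:
        return getattr(self, vital.value)

    def replace(self, vital: Vital, limits: Limits) -> "ThresholdSet":
        kwargs = {v.value: self.get(v) for v in Vital}
        kwargs[vital.value] = limits
        return ThresholdSet(**kwargs)


DEFAULT_THRESHOLDS = ThresholdSet()


@dataclass(frozen=True)
class Alarm:
    """A single alarm annunciation.

    ``window_start`` is the timestamp of the first abnormal sample of the
    streak that triggered the alarm; ``trigger_time`` is the timestamp of the
    sample at which the annunciation-delay requirement was met.
    """

    patient_id: str
    vital: Vital
    direction: Direction
    trigger_time: pd.Timestamp
    window_start: pd.Timestamp
    strategy_label: str = "baseline"

    def __post_init__(self) -> None:
        if self.trigger_time < self.window_start:
            raise ConfigurationError("alarm trigger_time precedes window_start")


def sort_alarms(alarms: list[Alarm]) -> list[Alarm]:
    """Stable chronological ordering; ties broken by vital then direction."""
    return sorted(alarms, key=lambda a: (a.trigger_time, a.vital.value, a.direction.value))


@dataclass(frozen=True)
class AdverseEventRecord:
    """Ground-truth adverse event: onset anchored at diagnostic confirmation.

    ``affected`` lists the (vital, direction) abnormalities the event can
    physiologically produce; it is the machine-readable surrogate for the
    clinical judgment used when classifying alarms.
    """

    patient_id: str
    ae_id: str
    confirmation_time: pd.Timestamp
    treatment_end: pd.Timestamp
    affected: frozenset[tuple[Vital, Direction]]
    severity: Severity

    def __post_init__(self) -> None:
        if not self.confirmation_time < self.treatment_end:
            raise AnnotationError(
                f"AE {self.ae_id}: confirmation_time must precede treatment_end"
            )


class AlarmLabel(str, enum.Enum):
    TP_EARLY = "TP_early"
    TP_LATE = "TP_late"
    FP = "FP"


@dataclass(frozen=True)
class ClassifiedAlarm:
    alarm: Alarm
    label: AlarmLabel
    ae_id: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.label is AlarmLabel.FP) == (self.ae_id is not None):
            raise AnnotationError("ae_id must be present iff the alarm is a true positive")

    @property
    def is_tp(self) -> bool:
        return self.label is not AlarmLabel.FP


@dataclass
class VitalTrace:
    """One patient's vital-sign recording on a fixed regular time grid.

    ``samples`` is indexed by timestamp (local clock time, naive) and has
    columns ``hr, rr, temp`` (float, NaN = missing) and ``hr_valid, rr_valid,
    temp_valid`` (bool). Gaps are represented as NaN rows on the grid, never
    as skipped rows. A sample is usable iff its value is present and its
    validity flag is set.
    """

    patient_id: str
    surgery_end: pd.Timestamp
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TRACE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise TraceError(f"trace {self.patient_id}: missing columns {missing}")
        if not isinstance(self.samples.index, pd.DatetimeIndex):
            raise TraceError(f"trace {self.patient_id}: index must be timestamps")

    # -- basic geometry -------------------------------------------------
    @property
    def times(self) -> pd.DatetimeIndex:
        return self.samples.index

    @property
    def start(self) -> pd.Timestamp:
        return self.times[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.times[-1]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def interval(self) -> pd.Timedelta:
        if self.n_samples < 2:
            return SAMPLING_INTERVAL
        return pd.Timedelta(self.times[1] - self.times[0])

    @property
    def duration(self) -> pd.Timedelta:
        """Total recording time (one interval per sample)."""
        return self.n_samples * self.interval

    # -- channel access -------------------------------------------------
    def values(self, vital: Vital) -> np.ndarray:
        return self.samples[VALUE_COLUMNS[vital]].to_numpy(dtype=float)

    def valid(self, vital: Vital) -> np.ndarray:
        """Usable-sample mask: value present AND flagged valid."""
        flags = self.samples[VALID_COLUMNS[vital]].to_numpy(dtype=bool)
        return flags & ~np.isnan(self.values(vital))

    def copy(self) -> "VitalTrace":
        return VitalTrace(self.patient_id, self.surgery_end, self.samples.copy())

    def validate(self) -> None:
        """Check grid regularity and physiological bounds; raise TraceError."""
        t = self.times
        if self.n_samples == 0:
            raise TraceError(f"trace {self.patient_id}: empty")
        if not t.is_monotonic_increasing or t.has_duplicates:
            raise TraceError(f"trace {self.patient_id}: timestamps not strictly increasing")
        if self.n_samples > 1:
            deltas = np.diff(t.asi8)
            if not (deltas == deltas[0]).all():
                raise TraceError(f"trace {self.patient_id}: irregular sampling grid")
        for vital in Vital:
            lo, hi = PHYSIOLOGICAL_BOUNDS[vital]
            v = self.values(vital)
            present = ~np.isnan(v)
            if present.any() and ((v[present] <= lo) | (v[present] >= hi)).any():
                raise TraceError(
                    f"trace {self.patient_id}: {vital.value} values outside ({lo}, {hi})"
                )


@dataclass(frozen=True)
class MetricsReport:
    """Performance metrics of one alarm-strategy run against annotated AEs.

    Sensitivities count distinct adverse events, not alarms: ``s_total`` is
    the percentage of AEs with at least one true-positive alarm, ``s_early``
    the percentage with at least one TP alarm before diagnostic confirmation.
    The total alarm rate is alarms per patient per day of recording; the
    false discovery rate is the percentage of alarms classified FP (absent
    when there are no alarms).
    """

    n_aes: int
    n_aes_detected: int
    n_aes_early: int
    n_alarms: int
    n_tp: int
    n_tp_early: int
    n_fp: int
    total_recording_days: float

    @property
    def s_total(self) -> float:
        return 100.0 * self.n_aes_detected / self.n_aes if self.n_aes else 0.0

    @property
    def s_early(self) -> float:
        return 100.0 * self.n_aes_early / self.n_aes if self.n_aes else 0.0

    @property
    def total_alarm_rate(self) -> float:
        return self.n_alarms / self.total_recording_days

    @property
    def false_discovery_rate(self) -> Optional[float]:
        if self.n_alarms == 0:
            return None
        return 100.0 * self.n_fp / self.n_alarms

    def summary(self) -> dict:
        """Display-rounded metrics (sensitivities to integers, TAR to 2 dp)."""
        fdr = self.false_discovery_rate
        return {
            "s_early": round_half_away(self.s_early),
            "s_total": round_half_away(self.s_total),
            "total_alarm_rate": round_half_away(self.total_alarm_rate, 2),
            "false_discovery_rate": None if fdr is None else round_half_away(fdr),
            "n_alarms": self.n_alarms,
            "n_tp": self.n_tp,
            "n_tp_early": self.n_tp_early,
            "n_fp": self.n_fp,
            "n_aes": self.n_aes,
            "total_recording_days": round(self.total_recording_days, 3),
        }


@dataclass(frozen=True)
class PScoreResult:
    """Banded performance score of a strategy relative to a reference.

    ``s_early_score`` and ``tar_score`` are integers in [-3, 3] assigned from
    the change in early-detection sensitivity and total alarm rate; the
    P-score is their sum, so positive values mean overall improvement over
    the reference strategy.
    """

    s_early_score: int
    tar_score: int
    s_early_ref: float
    tar_ref: float

    @property
    def p_score(self) -> int:
        return self.s_early_score + self.tar_score
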