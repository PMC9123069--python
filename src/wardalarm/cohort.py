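"""Synthetic postoperative cohort generator.

Produces per-patient vital-sign traces (HR, RR, axillary T on a 2-minute
grid) and adverse-event annotations with the statistical structure the
downstream analysis assumes: between-patient baseline variation, a circadian
day/night rhythm with its nadir in the night, a postoperative elevation
decaying over the first four days after surgery, white measurement noise,
missing samples, short movement-artifact bursts that remain flagged valid,
and adverse events that announce themselves as gradual vital-sign drifts
beginning hours before diagnostic confirmation.

The whole cohort is a deterministic function of (spec, seed): the same spec
with the same seed reproduces the cohort bit for bit.
"""
from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats

from .types import (
    AnnotationError,
    ConfigurationError,
    AdverseEventRecord,
    Direction,
    PHYSIOLOGICAL_BOUNDS,
    SAMPLING_INTERVAL,
    Severity,
    TRACE_COLUMNS,
    VALID_COLUMNS,
    VALUE_COLUMNS,
    Vital,
    VitalTrace,
)

#: Hour of day at which the circadian rhythm reaches its minimum.
CIRCADIAN_NADIR_HOUR = 3.0
#: Arbitrary local-clock epoch for generated recordings.
COHORT_EPOCH = pd.Timestamp("2024-01-01 00:00")
#: Severity mix of generated adverse events (Clavien-Dindo I / II / III).
SEVERITY_PROBS = {Severity.I: 6 / 18, Severity.II: 8 / 18, Severity.III: 4 / 18}


class PerVital(BaseModel):
    """A scalar parameter specified per vital channel."""

    model_config = ConfigDict(frozen=True)

    hr: float
    rr: float
    temp: float

    def get(self, vital: Vital) -> float:
        return getattr(self, vital.value)


class CohortSpec(BaseModel):
    """Parameters of the synthetic postoperative cohort.

    Defaults emulate the study conditions of a surgical-ward wearable
    monitoring cohort: 2-minute sampling, recording durations with median
    ~94 h in a 28-279 h range, and roughly half the patients developing an
    adverse event during monitoring. Vital-sign levels and variability are
    calibration choices in typical adult postoperative ranges.
    """

    model_config = ConfigDict(frozen=True)

    n_patients: int = Field(default=39, ge=1)
    sampling_interval_min: float = Field(default=2.0, gt=0)

    # Recording duration: log-normal (median, log-sd), truncated to a range.
    duration_median_h: float = Field(default=94.0, gt=0)
    duration_sigma: float = Field(default=0.45, ge=0)
    duration_min_h: float = Field(default=28.0, gt=0)
    duration_max_h: float = Field(default=279.0, gt=0)

    # Patient-level baselines (truncated-normal draws) and dynamics.
    baseline_mean: PerVital = PerVital(hr=78.0, rr=16.0, temp=36.8)
    baseline_sd: PerVital = PerVital(hr=8.0, rr=2.5, temp=0.3)
    circadian_amplitude: PerVital = PerVital(hr=8.0, rr=3.0, temp=0.5)
    postop_elevation: PerVital = PerVital(hr=0.10, rr=0.10, temp=0.01)
    postop_horizon_days: float = Field(default=4.0, gt=0)
    noise_sd: PerVital = PerVital(hr=3.0, rr=1.5, temp=0.15)

    # Data-quality degradation.
    missing_fraction: float = Field(default=0.10, ge=0, le=1)
    artifact_rate_per_day: float = Field(default=2.0, ge=0)
    artifact_magnitude: PerVital = PerVital(hr=25.0, rr=8.0, temp=0.0)
    artifact_max_samples: int = Field(default=5, ge=1)

    # Adverse events.
    ae_incidence: float = Field(default=0.5, ge=0, le=1)
    ae_effect: PerVital = PerVital(hr=40.0, rr=10.0, temp=1.5)
    ae_onset_lead_h: float = Field(default=12.0, ge=0)
    ae_treatment_h: float = Field(default=48.0, gt=0)
    ae_affected_probs: PerVital = PerVital(hr=0.8, rr=0.55, temp=0.45)

    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortSpec":
        if not self.duration_min_h <= self.duration_median_h <= self.duration_max_h:
            raise ConfigurationError(
                "duration_median_h must lie within [duration_min_h, duration_max_h]"
            )
        for name in ("hr", "rr", "temp"):
            for fld in ("baseline_sd", "circadian_amplitude", "noise_sd",
                        "postop_elevation", "artifact_magnitude", "ae_effect"):
                if getattr(getattr(self, fld), name) < 0:
                    raise ConfigurationError(f"{fld}.{name} must be >= 0")
            p = getattr(self.ae_affected_probs, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"ae_affected_probs.{name} must lie in [0, 1]")
        return self

    @property
    def interval(self) -> pd.Timedelta:
        return pd.Timedelta(minutes=self.sampling_interval_min)


def _draw_duration_h(spec: CohortSpec, rng: np.random.Generator) -> float:
    """Truncated log-normal recording duration in hours."""
    if spec.duration_sigma == 0:
        return float(np.clip(spec.duration_median_h, spec.duration_min_h, spec.duration_max_h))
    mu = np.log(spec.duration_median_h)
    for _ in range(1000):
        d = float(rng.lognormal(mu, spec.duration_sigma))
        if spec.duration_min_h <= d <= spec.duration_max_h:
            return d
    return float(np.clip(d, spec.duration_min_h, spec.duration_max_h))


def _draw_baseline(mean: float, sd: float, bounds: tuple[float, float],
                   rng: np.random.Generator) -> float:
    """Truncated-normal baseline; truncation keeps traces physiological."""
    lo, hi = bounds
    # keep one noise-width of headroom inside the hard bounds
    lo, hi = lo + 1.0, hi - 1.0
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _circadian(times: pd.DatetimeIndex, amplitude: float) -> np.ndarray:
    """Sinusoidal day/night variation; peak-to-trough equals ``amplitude``.

    The nadir falls at 03:00 local clock time (inside the 22:00-08:00 night
    window), the peak twelve hours later in the afternoon.
    """
    hours = times.hour.to_numpy() + times.minute.to_numpy() / 60.0
    return (amplitude / 2.0) * np.cos(2 * np.pi * (hours - CIRCADIAN_NADIR_HOUR - 12.0) / 24.0)


def _snap_to_grid(ts: pd.Timestamp, interval: pd.Timedelta) -> pd.Timestamp:
    return COHORT_EPOCH + ((ts - COHORT_EPOCH) // interval) * interval


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[VitalTrace], list[AdverseEventRecord]]:
    """Generate the synthetic cohort described by ``spec``.

    Returns ``n_patients`` traces on the regular grid plus the adverse-event
    annotations of the patients that drew an event. Each trace is
    baseline + circadian sinusoid + decaying postoperative elevation + white
    noise + artifact bursts, with samples missing at the configured fraction;
    event patients additionally receive a drift via
    :func:`inject_adverse_event`. Deterministic given ``spec.seed``.
    """
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(spec.n_patients)
    traces: list[VitalTrace] = []
    events: list[AdverseEventRecord] = []
    interval = spec.interval
    samples_per_day = pd.Timedelta(days=1) / interval

    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        patient_id = f"P{i + 1:03d}"

        duration_h = _draw_duration_h(spec, rng)
        n = max(2, int(round(duration_h * 60.0 / spec.sampling_interval_min)))
        start = _snap_to_grid(
            COHORT_EPOCH + pd.Timedelta(hours=float(rng.uniform(0.0, 24.0))), interval
        )
        times = pd.date_range(start, periods=n, freq=interval)
        surgery_end = start  # monitoring begins on return from theatre

        data: dict[str, np.ndarray] = {}
        elapsed_days = np.arange(n) * (spec.sampling_interval_min / (60.0 * 24.0))
        decay = np.where(
            elapsed_days < spec.postop_horizon_days,
            np.exp(-4.0 * elapsed_days / spec.postop_horizon_days),
            0.0,
        )
        for vital in Vital:
            base = _draw_baseline(
                spec.baseline_mean.get(vital),
                spec.baseline_sd.get(vital),
                PHYSIOLOGICAL_BOUNDS[vital],
                rng,
            )
            signal = np.full(n, base)
            signal = signal + _circadian(times, spec.circadian_amplitude.get(vital))
            signal = signal + base * spec.postop_elevation.get(vital) * decay
            if spec.noise_sd.get(vital) > 0:
                signal = signal + rng.normal(0.0, spec.noise_sd.get(vital), n)
            data[VALUE_COLUMNS[vital]] = signal
            data[VALID_COLUMNS[vital]] = np.ones(n, dtype=bool)

        # Movement-artifact bursts: short, upward-biased, still flagged valid.
        if spec.artifact_rate_per_day > 0:
            n_bursts = rng.poisson(spec.artifact_rate_per_day * n / samples_per_day)
            for _ in range(n_bursts):
                pos = int(rng.integers(0, n))
                length = int(rng.integers(1, spec.artifact_max_samples + 1))
                sl = slice(pos, min(pos + length, n))
                for vital in Vital:
                    mag = spec.artifact_magnitude.get(vital)
                    if mag > 0:
                        data[VALUE_COLUMNS[vital]][sl] += mag * rng.uniform(0.5, 1.0)

        # Missingness: independent per vital and sample, value absent and
        # validity flag cleared.
        for vital in Vital:
            if spec.missing_fraction > 0:
                gone = rng.random(n) < spec.missing_fraction
                data[VALUE_COLUMNS[vital]][gone] = np.nan
                data[VALID_COLUMNS[vital]][gone] = False

        # Clip the present values into the physiological plausibility bounds.
        for vital in Vital:
            lo, hi = PHYSIOLOGICAL_BOUNDS[vital]
            col = data[VALUE_COLUMNS[vital]]
            data[VALUE_COLUMNS[vital]] = np.clip(col, lo + 0.1, hi - 0.1)

        samples = pd.DataFrame(data, index=times, columns=TRACE_COLUMNS)
        trace = VitalTrace(patient_id, surgery_end, samples)

        # Adverse event: confirmation inside the recording (after the first
        # day where the recording allows), drift injected before confirmation.
        if rng.random() < spec.ae_incidence:
            lo_h = min(24.0, 0.5 * duration_h)
            conf_h = float(rng.uniform(lo_h, duration_h))
            confirmation = _snap_to_grid(start + pd.Timedelta(hours=conf_h), interval)
            treatment_end = confirmation + pd.Timedelta(hours=spec.ae_treatment_h)
            affected = set()
            for vital in Vital:
                if rng.random() < spec.ae_affected_probs.get(vital):
                    affected.add((vital, Direction.HIGH))
            if not affected:
                affected.add((Vital.HR, Direction.HIGH))
            severity = Severity(
                rng.choice(
                    [s.value for s in SEVERITY_PROBS],
                    p=list(SEVERITY_PROBS.values()),
                )
            )
            ae = AdverseEventRecord(
                patient_id=patient_id,
                ae_id=f"{patient_id}-AE1",
                confirmation_time=confirmation,
                treatment_end=treatment_end,
                affected=frozenset(affected),
                severity=severity,
            )
            effect = {v: spec.ae_effect.get(v) for v in Vital}
            trace = inject_adverse_event(
                trace, ae, effect, pd.Timedelta(hours=spec.ae_onset_lead_h)
            )
            events.append(ae)

        trace.validate()
        traces.append(trace)

    return traces, events


def inject_adverse_event(
    trace: VitalTrace,
    ae: AdverseEventRecord,
    effect: Mapping[Vital, float],
    onset_lead: pd.Timedelta,
) -> VitalTrace:
    """Superimpose an adverse event's vital-sign drift onto a trace.

    For each (vital, direction) in ``ae.affected`` a linear ramp is added,
    starting at ``confirmation_time - onset_lead``, reaching the full
    per-vital magnitude at confirmation, and sustained at that magnitude
    until ``treatment_end`` (signed by direction). Samples outside the event
    window and unaffected vitals are untouched. Returns a new trace.
    """
    if onset_lead < pd.Timedelta(0):
        raise AnnotationError("onset_lead must be non-negative")
    window_start = ae.confirmation_time - onset_lead
    if ae.treatment_end < trace.start or window_start > trace.end:
        raise AnnotationError(
            f"AE {ae.ae_id}: window outside the recording of {trace.patient_id}"
        )
    out = trace.copy()
    times = out.times
    seconds = (times - ae.confirmation_time) / pd.Timedelta(seconds=1)
    lead_s = onset_lead / pd.Timedelta(seconds=1)
    if lead_s > 0:
        ramp = np.clip(1.0 + np.asarray(seconds) / lead_s, 0.0, 1.0)
    else:
        ramp = (np.asarray(seconds) >= 0).astype(float)
    ramp = np.where(np.asarray(times > ae.treatment_end), 0.0, ramp)
    for vital, direction in ae.affected:
        mag = effect.get(vital, 0.0)
        if mag == 0:
            continue
        sign = 1.0 if direction is Direction.HIGH else -1.0
        col = VALUE_COLUMNS[vital]
        lo, hi = PHYSIOLOGICAL_BOUNDS[vital]
        shifted = out.samples[col].to_numpy(dtype=float) + sign * mag * ramp
        out.samples[col] = np.clip(shifted, lo + 0.1, hi - 0.1)
    return out
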