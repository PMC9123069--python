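"""Alarm classification against adverse events and performance scoring.

An alarm is a true positive for an adverse event when it fires in the
window from 24 h before diagnostic confirmation until the end of treatment,
in the same patient, and its (vital, direction) type is among the
abnormalities the event can physiologically produce. Alarms eligible for
several overlapping events are allocated to the event that developed latest
(latest confirmation time), never double counted. True positives firing
strictly before confirmation form the early subset (TP_early).

Strategy performance is summarized by two sensitivities (S_total, S_early,
percentages of adverse events with at least one TP / TP_early alarm), the
total alarm rate (alarms per patient per day) and the false discovery rate
(percentage of alarms that are FP), and compared to a reference strategy by
an integer performance score (P-score) built from banded changes in S_early
and total alarm rate.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .engine import AlarmConfig, run_cohort
from .strategies import SlopeTrend, StrategyParams
from .types import (
    AdverseEventRecord,
    Alarm,
    AlarmLabel,
    AnnotationError,
    ClassifiedAlarm,
    ConfigurationError,
    MetricsReport,
    PScoreResult,
    VitalTrace,
)

#: How long before diagnostic confirmation an alarm may still announce the event.
EARLY_WINDOW = pd.Timedelta(hours=24)

#: Reference performance of the original alarm strategy in the source study
#: (S_early percent, total alarm rate in alarms/patient/day).
ORIGINAL_REFERENCE = (39.0, 0.49)


# ---------------------------------------------------------------------------
# Classification and metrics
# ---------------------------------------------------------------------------

def classify_alarms(
    alarms: Sequence[Alarm],
    aes: Sequence[AdverseEventRecord],
    known_patients: Optional[Iterable[str]] = None,
) -> list[ClassifiedAlarm]:
    """Label every alarm TP_early, TP_late or FP against the annotated events.

    When ``known_patients`` is given, alarms or events referring to other
    patients raise :class:`AnnotationError`.
    """
    if known_patients is not None:
        known = set(known_patients)
        for a in alarms:
            if a.patient_id not in known:
                raise AnnotationError(f"alarm for unknown patient {a.patient_id}")
        for ae in aes:
            if ae.patient_id not in known:
                raise AnnotationError(f"adverse event for unknown patient {ae.patient_id}")

    by_patient: dict[str, list[AdverseEventRecord]] = {}
    for ae in aes:
        by_patient.setdefault(ae.patient_id, []).append(ae)

    out: list[ClassifiedAlarm] = []
    for alarm in alarms:
        eligible = [
            ae
            for ae in by_patient.get(alarm.patient_id, ())
            if ae.confirmation_time - EARLY_WINDOW
            <= alarm.trigger_time
            <= ae.treatment_end
            and (alarm.vital, alarm.direction) in ae.affected
        ]
        if not eligible:
            out.append(ClassifiedAlarm(alarm, AlarmLabel.FP))
            continue
        # Allocate to the event that developed latest in time.
        target = max(eligible, key=lambda ae: ae.confirmation_time)
        label = (
            AlarmLabel.TP_EARLY
            if alarm.trigger_time < target.confirmation_time
            else AlarmLabel.TP_LATE
        )
        out.append(ClassifiedAlarm(alarm, label, target.ae_id))
    return out


def filter_aes_to_recording(
    aes: Sequence[AdverseEventRecord], traces: Sequence[VitalTrace]
) -> list[AdverseEventRecord]:
    """Keep only events that presented or were treated while monitored.

    An event counts when its [confirmation, treatment end] interval overlaps
    the patient's recording window; events wholly outside any recording are
    excluded from sensitivity denominators.
    """
    windows = {t.patient_id: (t.start, t.end) for t in traces}
    kept = []
    for ae in aes:
        w = windows.get(ae.patient_id)
        if w is None:
            continue
        start, end = w
        if ae.confirmation_time <= end and ae.treatment_end >= start:
            kept.append(ae)
    return kept


def total_recording_days(traces: Sequence[VitalTrace]) -> float:
    return float(sum((t.duration / pd.Timedelta(days=1) for t in traces), 0.0))


def compute_metrics(
    classified: Sequence[ClassifiedAlarm],
    aes: Sequence[AdverseEventRecord],
    total_recording: float,
) -> MetricsReport:
    """Aggregate classified alarms into the four performance metrics.

    ``total_recording`` is in patient-days. Sensitivities count distinct
    adverse events, not alarms; with zero alarms the false discovery rate is
    absent (None), not zero.
    """
    if total_recording <= 0:
        raise ConfigurationError("total_recording must be positive")
    detected = {c.ae_id for c in classified if c.is_tp}
    early = {c.ae_id for c in classified if c.label is AlarmLabel.TP_EARLY}
    ae_ids = {ae.ae_id for ae in aes}
    n_tp = sum(1 for c in classified if c.is_tp)
    n_tp_early = sum(1 for c in classified if c.label is AlarmLabel.TP_EARLY)
    n_fp = sum(1 for c in classified if not c.is_tp)
    return MetricsReport(
        n_aes=len(ae_ids),
        n_aes_detected=len(detected & ae_ids),
        n_aes_early=len(early & ae_ids),
        n_alarms=len(classified),
        n_tp=n_tp,
        n_tp_early=n_tp_early,
        n_fp=n_fp,
        total_recording_days=float(total_recording),
    )


# ---------------------------------------------------------------------------
# Performance score
# ---------------------------------------------------------------------------

# Band edges are evaluated on the difference to the reference, rounded to
# 1e-9 to absorb floating-point noise at exact band boundaries.
_EDGE_DECIMALS = 9


def _s_early_score(s_early: float, ref: float) -> int:
    d = round(s_early - ref, _EDGE_DECIMALS)
    if d == 0:
        return 0
    if d <= -10:
        return -3
    if d <= -5:
        return -2
    if d < 0:
        return -1
    if d <= 5:
        return 1
    if d <= 10:
        return 2
    return 3


def _tar_score(tar: float, ref: float) -> int:
    d = round(tar - ref, _EDGE_DECIMALS)
    if d == 0:
        return 0
    if d > 0.5:
        return -3
    if d > 0.25:
        return -2
    if d > 0:
        return -1
    if d > -0.25:
        return 1
    if d > -0.5:
        return 2
    return 3


def compute_pscore(
    s_early: float,
    tar: float,
    s_early_ref: float = ORIGINAL_REFERENCE[0],
    tar_ref: float = ORIGINAL_REFERENCE[1],
) -> PScoreResult:
    """Banded performance score of (S_early, TAR) against a reference.

    S_early sub-score: 5-percentage-point bands around the reference, from
    -3 (S_early <= ref - 10) to +3 (S_early > ref + 10), with exact equality
    scoring 0. TAR sub-score: 0.25 alarms/patient/day bands, from -3
    (TAR > ref + 0.5) to +3 (TAR <= ref - 0.5), equality scoring 0. The
    P-score is their sum.
    """
    for name, v in (("s_early", s_early), ("tar", tar),
                    ("s_early_ref", s_early_ref), ("tar_ref", tar_ref)):
        if not pd.notna(v) or v < 0:
            raise ConfigurationError(f"{name} must be finite and non-negative")
    return PScoreResult(
        s_early_score=_s_early_score(s_early, s_early_ref),
        tar_score=_tar_score(tar, tar_ref),
        s_early_ref=s_early_ref,
        tar_ref=tar_ref,
    )


# ---------------------------------------------------------------------------
# Parameter selection, combinations, backward elimination
# ---------------------------------------------------------------------------

def select_optimal_params(
    candidates: Sequence[tuple[StrategyParams, MetricsReport]],
    s_early_ref: float,
    tar_ref: float,
) -> StrategyParams:
    """Pick the candidate parameter set with the highest P-score.

    Ties are broken by lowest false discovery rate (absent FDR, i.e. no
    alarms at all, ranks best), then by smallest modification magnitude,
    then by candidate order.
    """
    if not candidates:
        raise ConfigurationError("select_optimal_params requires at least one candidate")

    def key(item: tuple[int, tuple[StrategyParams, MetricsReport]]):
        idx, (params, metrics) = item
        p = compute_pscore(metrics.s_early, metrics.total_alarm_rate, s_early_ref, tar_ref)
        fdr = metrics.false_discovery_rate
        return (-p.p_score, fdr if fdr is not None else 0.0, params.magnitude, idx)

    best = min(enumerate(candidates), key=key)
    return best[1][0]


@dataclass(frozen=True)
class StrategyRun:
    """Result of running and scoring one strategy set over a cohort."""

    labels: tuple[str, ...]
    metrics: MetricsReport
    pscore: PScoreResult


def evaluate_strategy_set(
    traces: Sequence[VitalTrace],
    aes: Sequence[AdverseEventRecord],
    strategies: Sequence[StrategyParams],
    s_early_ref: float,
    tar_ref: float,
    base_config: Optional[AlarmConfig] = None,
) -> StrategyRun:
    """Detect, classify and score one strategy combination over a cohort."""
    base = base_config or AlarmConfig()
    config = AlarmConfig(base.thresholds, base.n_abnormal, base.n_rearm, tuple(strategies))
    alarms = run_cohort(traces, config)
    included = filter_aes_to_recording(aes, traces)
    classified = classify_alarms(alarms, included, known_patients=[t.patient_id for t in traces])
    metrics = compute_metrics(classified, included, total_recording_days(traces))
    pscore = compute_pscore(metrics.s_early, metrics.total_alarm_rate, s_early_ref, tar_ref)
    labels = tuple(s.label for s in strategies) if strategies else ("baseline",)
    return StrategyRun(labels, metrics, pscore)


_ROMAN_ORDER = {"I": 0, "II": 1, "III": 2, "IV": 3, "V": 4}


def _check_pool(pool: Sequence[StrategyParams]) -> None:
    if any(isinstance(s, SlopeTrend) for s in pool):
        raise ConfigurationError(
            "the slope strategy (VI) cannot participate in combinations"
        )


def evaluate_combinations(
    traces: Sequence[VitalTrace],
    aes: Sequence[AdverseEventRecord],
    pool: Sequence[StrategyParams],
    s_early_ref: float,
    tar_ref: float,
    base_config: Optional[AlarmConfig] = None,
) -> list[StrategyRun]:
    """Score every non-empty subset of the strategy pool (2^k - 1 rows).

    The pool must be drawn from the threshold strategies I-V; subsets are
    applied cumulatively (all modifiers active at once).
    """
    _check_pool(pool)
    ordered = sorted(pool, key=lambda s: _ROMAN_ORDER[s.label])
    rows: list[StrategyRun] = []
    for size in range(1, len(ordered) + 1):
        for subset in itertools.combinations(ordered, size):
            rows.append(
                evaluate_strategy_set(
                    traces, aes, subset, s_early_ref, tar_ref, base_config
                )
            )
    return rows


def backward_elimination(
    traces: Sequence[VitalTrace],
    aes: Sequence[AdverseEventRecord],
    start_set: Sequence[StrategyParams],
    s_early_ref: float,
    tar_ref: float,
    base_config: Optional[AlarmConfig] = None,
) -> list[StrategyRun]:
    """Stepwise backward elimination from the full strategy combination.

    Starting from ``start_set``, each step scores every subset obtained by
    removing one strategy and keeps the one with the highest P-score (ties:
    lowest false discovery rate, then removal of the lowest-numbered
    strategy). The returned path runs from the full set down to a single
    strategy.
    """
    if not start_set:
        raise ConfigurationError("backward elimination needs a non-empty start set")
    _check_pool(start_set)
    current = sorted(start_set, key=lambda s: _ROMAN_ORDER[s.label])
    path = [
        evaluate_strategy_set(traces, aes, current, s_early_ref, tar_ref, base_config)
    ]
    while len(current) > 1:
        best_subset = None
        best_key = None
        for i in range(len(current)):
            subset = current[:i] + current[i + 1 :]
            run = evaluate_strategy_set(
                traces, aes, subset, s_early_ref, tar_ref, base_config
            )
            fdr = run.metrics.false_discovery_rate
            key = (-run.pscore.p_score, fdr if fdr is not None else 0.0, i)
            if best_key is None or key < best_key:
                best_key = key
                best_subset = (subset, run)
        assert best_subset is not None
        current, run = best_subset
        path.append(run)
    return path
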