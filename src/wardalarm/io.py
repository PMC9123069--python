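"""CSV/JSON/YAML interfaces for traces, alarms, adverse events and configs.

One CSV dialect throughout: comma-separated, UTF-8, header row required,
timestamps as ISO-8601 local clock time (no UTC conversion — the day/night
strategies are defined on clock time). Empty cells mean missing values.

The trace file carries no surgery-end column, so cohorts are written as a
pair: ``traces.csv`` plus a ``patients.csv`` sidecar mapping each patient to
their surgery-end timestamp. When the sidecar is absent, surgery end is
taken as the first recorded timestamp.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .cohort import CohortSpec
from .engine import AlarmConfig
from .evaluation import ORIGINAL_REFERENCE
from .strategies import (
    AnnunciationDelay,
    DaytimeElevation,
    IndividualizedThresholds,
    NighttimeReduction,
    PostopElevation,
    SlopeTrend,
    StrategyParams,
)
from .types import (
    AdverseEventRecord,
    Alarm,
    AlarmLabel,
    ClassifiedAlarm,
    ConfigurationError,
    Direction,
    MetricsReport,
    ParseError,
    PScoreResult,
    Severity,
    TRACE_COLUMNS,
    Vital,
    VitalTrace,
    round_half_away,
)

TRACE_FILE_COLUMNS = ["patient_id", "timestamp"] + TRACE_COLUMNS
ALARM_FILE_COLUMNS = [
    "patient_id", "vital", "direction", "trigger_time", "window_start", "strategy_label",
]
AE_FILE_COLUMNS = [
    "patient_id", "ae_id", "confirmation_time", "treatment_end", "affected", "severity",
]


def _parse_timestamp(value: str, context: str) -> pd.Timestamp:
    try:
        ts = pd.Timestamp(value)
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{context}: timestamp {value!r} is not ISO-8601") from exc
    if ts.tzinfo is not None:
        ts = ts.tz_localize(None)
    return ts


def _require_columns(df: pd.DataFrame, expected: Sequence[str], path: Path) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")


# ---------------------------------------------------------------------------
# Traces
# ---------------------------------------------------------------------------

def write_traces(path, traces: Sequence[VitalTrace]) -> None:
    """Write a cohort to one CSV (all patients, long format); path or buffer."""
    frames = []
    for t in traces:
        df = t.samples.reset_index(names="timestamp")
        df.insert(0, "patient_id", t.patient_id)
        frames.append(df)
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=TRACE_FILE_COLUMNS)
    out["timestamp"] = out["timestamp"].map(lambda ts: pd.Timestamp(ts).isoformat())
    out.to_csv(path, index=False, columns=TRACE_FILE_COLUMNS)


def write_patients(path: Path | str, traces: Sequence[VitalTrace]) -> None:
    """Write the surgery-end sidecar for a cohort."""
    pd.DataFrame(
        {
            "patient_id": [t.patient_id for t in traces],
            "surgery_end": [t.surgery_end.isoformat() for t in traces],
        }
    ).to_csv(path, index=False)


def read_traces(
    path: Path | str, patients_path: Optional[Path | str] = None
) -> list[VitalTrace]:
    """Read a cohort CSV (optionally with its surgery-end sidecar)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    _require_columns(df, TRACE_FILE_COLUMNS, path)

    surgery_ends: dict[str, pd.Timestamp] = {}
    if patients_path is not None:
        pdf = pd.read_csv(patients_path)
        _require_columns(pdf, ["patient_id", "surgery_end"], Path(patients_path))
        for row, rec in pdf.iterrows():
            surgery_ends[str(rec["patient_id"])] = _parse_timestamp(
                rec["surgery_end"], f"{patients_path} row {row + 2}"
            )

    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: column timestamp: {exc}") from exc
    for col in ("hr_valid", "rr_valid", "temp_valid"):
        df[col] = df[col].astype(bool)

    traces = []
    for patient_id, group in df.groupby("patient_id", sort=False):
        samples = group.set_index("timestamp")[TRACE_COLUMNS]
        samples.index.name = None
        pid = str(patient_id)
        surgery_end = surgery_ends.get(pid, samples.index[0])
        trace = VitalTrace(pid, surgery_end, samples)
        trace.validate()
        traces.append(trace)
    return traces


# ---------------------------------------------------------------------------
# Alarms
# ---------------------------------------------------------------------------

def write_alarms(path: Path | str, alarms: Sequence[Alarm]) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": a.patient_id,
                "vital": a.vital.value,
                "direction": a.direction.value,
                "trigger_time": a.trigger_time.isoformat(),
                "window_start": a.window_start.isoformat(),
                "strategy_label": a.strategy_label,
            }
            for a in alarms
        ],
        columns=ALARM_FILE_COLUMNS,
    ).to_csv(path, index=False)


def read_alarms(path: Path | str) -> list[Alarm]:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    _require_columns(df, ALARM_FILE_COLUMNS, path)
    alarms = []
    for row, rec in df.iterrows():
        ctx = f"{path} row {row + 2}"
        try:
            vital = Vital(rec["vital"])
            direction = Direction(rec["direction"])
        except ValueError as exc:
            raise ParseError(f"{ctx}: {exc}") from exc
        alarms.append(
            Alarm(
                patient_id=str(rec["patient_id"]),
                vital=vital,
                direction=direction,
                trigger_time=_parse_timestamp(rec["trigger_time"], ctx),
                window_start=_parse_timestamp(rec["window_start"], ctx),
                strategy_label=str(rec["strategy_label"]),
            )
        )
    return alarms


# ---------------------------------------------------------------------------
# Adverse events
# ---------------------------------------------------------------------------

def _format_affected(affected: frozenset[tuple[Vital, Direction]]) -> str:
    pairs = sorted((v.value, d.value) for v, d in affected)
    return ";".join(f"{v}:{d}" for v, d in pairs)


def _parse_affected(text: str, context: str) -> frozenset[tuple[Vital, Direction]]:
    pairs = set()
    for item in str(text).split(";"):
        item = item.strip()
        if not item:
            continue
        try:
            v, d = item.split(":")
            pairs.add((Vital(v), Direction(d)))
        except ValueError as exc:
            raise ParseError(f"{context}: column affected: bad entry {item!r}") from exc
    if not pairs:
        raise ParseError(f"{context}: column affected is empty")
    return frozenset(pairs)


def write_aes(path: Path | str, aes: Sequence[AdverseEventRecord]) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": ae.patient_id,
                "ae_id": ae.ae_id,
                "confirmation_time": ae.confirmation_time.isoformat(),
                "treatment_end": ae.treatment_end.isoformat(),
                "affected": _format_affected(ae.affected),
                "severity": ae.severity.value,
            }
            for ae in aes
        ],
        columns=AE_FILE_COLUMNS,
    ).to_csv(path, index=False)


def read_aes(path: Path | str) -> list[AdverseEventRecord]:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    _require_columns(df, AE_FILE_COLUMNS, path)
    aes = []
    for row, rec in df.iterrows():
        ctx = f"{path} row {row + 2}"
        try:
            severity = Severity(str(rec["severity"]))
        except ValueError as exc:
            raise ParseError(f"{ctx}: column severity: {exc}") from exc
        aes.append(
            AdverseEventRecord(
                patient_id=str(rec["patient_id"]),
                ae_id=str(rec["ae_id"]),
                confirmation_time=_parse_timestamp(rec["confirmation_time"], ctx),
                treatment_end=_parse_timestamp(rec["treatment_end"], ctx),
                affected=_parse_affected(rec["affected"], ctx),
                severity=severity,
            )
        )
    return aes


# ---------------------------------------------------------------------------
# Classified alarms
# ---------------------------------------------------------------------------

def write_classified(path: Path | str, classified: Sequence[ClassifiedAlarm]) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": c.alarm.patient_id,
                "vital": c.alarm.vital.value,
                "direction": c.alarm.direction.value,
                "trigger_time": c.alarm.trigger_time.isoformat(),
                "label": c.label.value,
                "ae_id": c.ae_id or "",
            }
            for c in classified
        ],
        columns=["patient_id", "vital", "direction", "trigger_time", "label", "ae_id"],
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

class ReferenceMetrics(BaseModel):
    """Reference (S_early %, total alarm rate) the P-score compares against."""

    model_config = ConfigDict(frozen=True)

    s_early: float = Field(default=ORIGINAL_REFERENCE[0], ge=0)
    tar: float = Field(default=ORIGINAL_REFERENCE[1], ge=0)


class RunConfig(BaseModel):
    """Top-level run configuration loadable from YAML or JSON."""

    model_config = ConfigDict(frozen=True)

    cohort: CohortSpec = CohortSpec()
    strategies: list[dict[str, Any]] = Field(default_factory=list)
    n_abnormal: int = Field(default=7, ge=1)
    n_rearm: int = Field(default=5, ge=0)
    reference: ReferenceMetrics = ReferenceMetrics()
    seed: int = 0
    log_level: str = "WARNING"


_FRACTION_VITALS = {"hr": Vital.HR, "rr": Vital.RR, "temp": Vital.TEMP}


def _per_vital_fractions(raw: Any, name: str) -> dict[Vital, float]:
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{name} must map vitals to fractions")
    out = {}
    for k, v in raw.items():
        if k not in _FRACTION_VITALS:
            raise ConfigurationError(f"{name}: unknown vital {k!r}")
        out[_FRACTION_VITALS[k]] = float(v)
    return out


def strategy_from_dict(entry: dict[str, Any]) -> StrategyParams:
    """Build a strategy parameter set from its config mapping.

    Parameter keys follow the field names of the strategy table: cdf_low,
    cdf_high, po_increase, l_interval, dt_increase, nt_decrease, t_slope_h.
    Fractions are expressed as fractions (0.05 = 5 %).
    """
    entry = dict(entry)
    name = str(entry.pop("strategy", "")).upper()
    try:
        if name == "I":
            return IndividualizedThresholds(
                cdf_low=float(entry.pop("cdf_low", 1.0)),
                cdf_high=float(entry.pop("cdf_high", 99.0)),
            )
        if name == "II":
            kwargs = {}
            if "po_increase" in entry:
                kwargs["po_increase"] = _per_vital_fractions(
                    entry.pop("po_increase"), "po_increase"
                )
            return PostopElevation(**kwargs)
        if name == "III":
            return AnnunciationDelay(int(entry.pop("l_interval", 12)))
        if name == "IV":
            kwargs = {}
            if "dt_increase" in entry:
                kwargs["dt_increase"] = _per_vital_fractions(
                    entry.pop("dt_increase"), "dt_increase"
                )
            return DaytimeElevation(**kwargs)
        if name == "V":
            kwargs = {}
            if "nt_decrease" in entry:
                kwargs["nt_decrease"] = _per_vital_fractions(
                    entry.pop("nt_decrease"), "nt_decrease"
                )
            return NighttimeReduction(**kwargs)
        if name == "VI":
            kwargs = {}
            if "t_slope_h" in entry:
                kwargs["t_slope"] = pd.Timedelta(hours=float(entry.pop("t_slope_h")))
            if "slope_limits" in entry:
                kwargs["slope_limits"] = _per_vital_fractions(
                    entry.pop("slope_limits"), "slope_limits"
                )
            return SlopeTrend(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"strategy {name}: {exc}") from exc
    raise ConfigurationError(f"unknown strategy {name!r} (expected I..VI)")


def alarm_config_from_run(config: RunConfig) -> AlarmConfig:
    strategies = tuple(strategy_from_dict(e) for e in config.strategies)
    return AlarmConfig(
        n_abnormal=config.n_abnormal, n_rearm=config.n_rearm, strategies=strategies
    )


def load_run_config(path: Path | str) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    try:
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    try:
        return RunConfig.model_validate(raw or {})
    except ValidationError as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def report_dict(metrics: MetricsReport, pscore: Optional[PScoreResult] = None) -> dict:
    out = dict(metrics.summary())
    if pscore is not None:
        out.update(
            {
                "s_early_score": pscore.s_early_score,
                "tar_score": pscore.tar_score,
                "p_score": pscore.p_score,
                "s_early_ref": pscore.s_early_ref,
                "tar_ref": pscore.tar_ref,
            }
        )
    return out


def render_report(metrics: MetricsReport, pscore: Optional[PScoreResult] = None) -> str:
    """Human-readable summary table of one strategy run."""
    fdr = metrics.false_discovery_rate
    lines = [
        f"Adverse events monitored      : {metrics.n_aes}",
        f"Alarms (TP early / TP / FP)   : {metrics.n_alarms} "
        f"({metrics.n_tp_early} / {metrics.n_tp} / {metrics.n_fp})",
        f"S_early                       : {round_half_away(metrics.s_early):.0f} %",
        f"S_total                       : {round_half_away(metrics.s_total):.0f} %",
        f"Total alarm rate              : "
        f"{round_half_away(metrics.total_alarm_rate, 2):.2f} alarms/patient/day",
        "False discovery rate          : "
        + ("n/a" if fdr is None else f"{round_half_away(fdr):.0f} %"),
    ]
    if pscore is not None:
        lines.append(
            f"P-score vs ref (S_early {pscore.s_early_ref:g} %, "
            f"TAR {pscore.tar_ref:g}) : {pscore.p_score:+d} "
            f"(S_early {pscore.s_early_score:+d}, TAR {pscore.tar_score:+d})"
        )
    return "\n".join(lines)
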