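"""Shared fixtures-in-code and independent oracles for the test suite.

The oracles deliberately use different algorithmic structure from the
library (run enumeration instead of streaming state, exhaustive pair loops,
exact rational arithmetic) so that agreement is evidence, not tautology.
"""
from __future__ import annotations

from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from wardalarm import (
    AdverseEventRecord,
    Alarm,
    Direction,
    Severity,
    Vital,
    VitalTrace,
)
from wardalarm.types import TRACE_COLUMNS, VALID_COLUMNS, VALUE_COLUMNS

T0 = pd.Timestamp("2024-01-01 00:00")
STEP = pd.Timedelta(minutes=2)


def make_trace(
    hr=70.0,
    rr=14.0,
    temp=36.8,
    n: Optional[int] = None,
    start: pd.Timestamp = T0,
    patient_id: str = "P1",
    surgery_end: Optional[pd.Timestamp] = None,
    hr_valid=None,
    rr_valid=None,
    temp_valid=None,
) -> VitalTrace:
    """Build a trace from scalars or arrays on the 2-minute grid."""
    arrays = {}
    lengths = [len(a) for a in (hr, rr, temp) if np.ndim(a) > 0]
    if n is None:
        n = lengths[0] if lengths else 720
    times = pd.date_range(start, periods=n, freq=STEP)
    for vital, values, valid in (
        (Vital.HR, hr, hr_valid),
        (Vital.RR, rr, rr_valid),
        (Vital.TEMP, temp, temp_valid),
    ):
        v = np.broadcast_to(np.asarray(values, dtype=float), (n,)).copy()
        arrays[VALUE_COLUMNS[vital]] = v
        if valid is None:
            flags = np.ones(n, dtype=bool)
        else:
            flags = np.broadcast_to(np.asarray(valid, dtype=bool), (n,)).copy()
        arrays[VALID_COLUMNS[vital]] = flags
    samples = pd.DataFrame(arrays, index=times, columns=TRACE_COLUMNS)
    return VitalTrace(patient_id, surgery_end or start, samples)


def make_ae(
    patient_id="P1",
    ae_id="AE1",
    confirmation=T0 + pd.Timedelta(hours=48),
    treatment_end=None,
    affected=((Vital.HR, Direction.HIGH),),
    severity=Severity.II,
) -> AdverseEventRecord:
    return AdverseEventRecord(
        patient_id=patient_id,
        ae_id=ae_id,
        confirmation_time=confirmation,
        treatment_end=treatment_end or confirmation + pd.Timedelta(hours=24),
        affected=frozenset(affected),
        severity=severity,
    )


# ---------------------------------------------------------------------------
# Streak-rule oracle: maximal-run enumeration
# ---------------------------------------------------------------------------

def oracle_streak_alarms(
    values: np.ndarray,
    usable: np.ndarray,
    lower: Optional[float],
    upper: Optional[float],
    direction: Direction,
    n_abnormal: int,
    n_rearm: int,
) -> list[tuple[int, int]]:
    """Literal application of the annunciation/re-arm rules.

    Drops unusable samples, classifies each remaining sample as abnormal in
    the requested direction ('A'), in the normal range ('N') or abnormal the
    other way ('O'), decomposes the symbol sequence into maximal runs, and
    applies the rules run by run. Returns (window_start_idx, trigger_idx)
    pairs as indices into the original sample grid.
    """
    idx = [i for i in range(len(values)) if usable[i]]
    syms = []
    for i in idx:
        v = values[i]
        hi = upper is not None and v > upper
        lo = lower is not None and v < lower
        if direction is Direction.HIGH:
            syms.append("A" if hi else ("O" if lo else "N"))
        else:
            syms.append("A" if lo else ("O" if hi else "N"))

    runs: list[tuple[str, int, int]] = []  # (symbol, start offset, length)
    pos = 0
    while pos < len(syms):
        end = pos
        while end < len(syms) and syms[end] == syms[pos]:
            end += 1
        runs.append((syms[pos], pos, end - pos))
        pos = end

    alarms: list[tuple[int, int]] = []
    armed = True
    for sym, start, length in runs:
        if sym == "A" and armed:
            if n_rearm == 0:
                fired = 0
                while (fired + 1) * n_abnormal <= length:
                    w = start + fired * n_abnormal
                    alarms.append((idx[w], idx[w + n_abnormal - 1]))
                    fired += 1
            elif length >= n_abnormal:
                alarms.append((idx[start], idx[start + n_abnormal - 1]))
                armed = False
        elif sym == "N" and not armed and length >= n_rearm:
            armed = True
    return alarms


# ---------------------------------------------------------------------------
# Classification oracle: exhaustive pair enumeration
# ---------------------------------------------------------------------------

def oracle_classify(
    alarms: Sequence[Alarm], aes: Sequence[AdverseEventRecord]
) -> list[tuple[str, Optional[str]]]:
    """(label, ae_id) per alarm from a literal double loop over all pairs."""
    window = pd.Timedelta(hours=24)
    out = []
    for alarm in alarms:
        best = None
        for ae in aes:
            if ae.patient_id != alarm.patient_id:
                continue
            if not (ae.confirmation_time - window <= alarm.trigger_time <= ae.treatment_end):
                continue
            if (alarm.vital, alarm.direction) not in ae.affected:
                continue
            if best is None or ae.confirmation_time > best.confirmation_time:
                best = ae
        if best is None:
            out.append(("FP", None))
        elif alarm.trigger_time < best.confirmation_time:
            out.append(("TP_early", best.ae_id))
        else:
            out.append(("TP_late", best.ae_id))
    return out


# ---------------------------------------------------------------------------
# Performance-score oracle: exact rational band table
# ---------------------------------------------------------------------------

def oracle_pscore(s_early, tar, s_early_ref, tar_ref) -> int:
    """Piecewise re-statement of the published score bands in exact arithmetic."""
    s = Fraction(str(s_early))
    sr = Fraction(str(s_early_ref))
    t = Fraction(str(tar))
    tr = Fraction(str(tar_ref))

    if s == sr:
        s_score = 0
    elif s <= sr - 10:
        s_score = -3
    elif sr - 10 < s <= sr - 5:
        s_score = -2
    elif sr - 5 < s <= sr:
        s_score = -1
    elif sr < s <= sr + 5:
        s_score = 1
    elif sr + 5 < s <= sr + 10:
        s_score = 2
    else:
        s_score = 3

    q = Fraction(1, 4)
    h = Fraction(1, 2)
    if t == tr:
        t_score = 0
    elif t > tr + h:
        t_score = -3
    elif tr + q < t <= tr + h:
        t_score = -2
    elif tr < t <= tr + q:
        t_score = -1
    elif tr - q < t <= tr:
        t_score = 1
    elif tr - h < t <= tr - q:
        t_score = 2
    else:
        t_score = 3

    return s_score + t_score
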