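"""Adaptive alarm-strategy parameterizations.

Six modifications of the classical threshold alarm algorithm are supported,
conventionally labelled with roman numerals:

I   threshold individualization from each patient's first-24-h vital-sign
    distribution (percentile pair ``cdf_low``/``cdf_high``),
II  postoperative elevation of upper thresholds for the first four days
    after surgery (``po_increase`` fraction per vital),
III lengthened annunciation delay (``l_interval`` successive abnormal
    measurements instead of the default 7),
IV  daytime (08:00-22:00) elevation of the upper HR/RR thresholds
    (``dt_increase``),
V   nighttime (22:00-08:00) reduction of the lower HR/RR thresholds
    (``nt_decrease``),
VI  slope-based alarms from a rolling linear-regression trend over a window
    ``t_slope``, ignoring absolute levels (incompatible with I-V).

Each class carries a ``magnitude`` used as the smallest-modification
tie-break when selecting optimal parameters.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .types import ConfigurationError, Vital

# Clock-time boundaries for the day/night strategies.
DAY_START_HOUR = 8
DAY_END_HOUR = 22
# Postoperative window length for strategy II.
POSTOP_WINDOW = pd.Timedelta(hours=96)


@dataclass(frozen=True)
class StrategyParams:
    """Base class for strategy parameter sets."""

    label: str = field(default="", init=False)

    @property
    def magnitude(self) -> float:  # pragma: no cover - overridden
        raise NotImplementedError


@dataclass(frozen=True)
class IndividualizedThresholds(StrategyParams):
    """Strategy I: replace population thresholds by per-patient percentiles.

    Percentiles are taken from the empirical distribution of each vital over
    the first 24 h of recording; default thresholds apply during those first
    24 h. Temperature keeps no lower limit.
    """

    cdf_low: float = 1.0  # percentile, %
    cdf_high: float = 99.0  # percentile, %

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", "I")
        if not (0.0 < self.cdf_low < 50.0):
            raise ConfigurationError("cdf_low must lie in (0, 50) percent")
        if not (50.0 < self.cdf_high < 100.0):
            raise ConfigurationError("cdf_high must lie in (50, 100) percent")

    @property
    def magnitude(self) -> float:
        # Distance of the percentile pair from the distribution extremes.
        return self.cdf_low + (100.0 - self.cdf_high)


@dataclass(frozen=True)
class PostopElevation(StrategyParams):
    """Strategy II: raise upper thresholds during the first 4 postoperative days."""

    po_increase: Mapping[Vital, float] = field(
        default_factory=lambda: {Vital.HR: 0.05, Vital.RR: 0.05, Vital.TEMP: 0.01}
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", "II")
        _check_fractions(self.po_increase, "po_increase")

    @property
    def magnitude(self) -> float:
        return sum(self.po_increase.values())


@dataclass(frozen=True)
class AnnunciationDelay(StrategyParams):
    """Strategy III: require a longer streak of abnormal measurements."""

    l_interval: int = 12

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", "III")
        if self.l_interval < 1:
            raise ConfigurationError("l_interval must be >= 1")

    @property
    def magnitude(self) -> float:
        return float(self.l_interval)


@dataclass(frozen=True)
class DaytimeElevation(StrategyParams):
    """Strategy IV: raise upper HR/RR thresholds during daytime (08:00-22:00)."""

    dt_increase: Mapping[Vital, float] = field(
        default_factory=lambda: {Vital.HR: 0.05, Vital.RR: 0.15}
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", "IV")
        _check_fractions(self.dt_increase, "dt_increase")
        if Vital.TEMP in self.dt_increase:
            raise ConfigurationError("dt_increase applies to HR and RR only")

    @property
    def magnitude(self) -> float:
        return sum(self.dt_increase.values())


@dataclass(frozen=True)
class NighttimeReduction(StrategyParams):
    """Strategy V: lower the lower HR/RR thresholds during nighttime (22:00-08:00)."""

    nt_decrease: Mapping[Vital, float] = field(
        default_factory=lambda: {Vital.HR: 0.10, Vital.RR: 0.25}
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", "V")
        _check_fractions(self.nt_decrease, "nt_decrease")
        if Vital.TEMP in self.nt_decrease:
            raise ConfigurationError("nt_decrease applies to HR and RR only")

    @property
    def magnitude(self) -> float:
        return sum(self.nt_decrease.values())


@dataclass(frozen=True)
class SlopeTrend(StrategyParams):
    """Strategy VI: alarm on the rolling linear-regression slope alone.

    The abnormality condition is |slope| x t_slope > limit, i.e. the fitted
    change over one window length exceeds the per-vital limit (default
    +-15 beats/min for HR, +-10 breaths/min for RR, +-1 C for T).
    """

    t_slope: pd.Timedelta = pd.Timedelta(hours=4)
    slope_limits: Mapping[Vital, float] = field(
        default_factory=lambda: {Vital.HR: 15.0, Vital.RR: 10.0, Vital.TEMP: 1.0}
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", "VI")
        if self.t_slope <= pd.Timedelta(0):
            raise ConfigurationError("t_slope must be positive")
        for v, lim in self.slope_limits.items():
            if lim < 0:
                raise ConfigurationError(f"slope limit for {v.value} must be >= 0")

    @property
    def magnitude(self) -> float:
        # Shorter windows react to smaller excursions: larger modification.
        return 1.0 / (self.t_slope / pd.Timedelta(hours=1))


def _check_fractions(mapping: Mapping[Vital, float], name: str) -> None:
    for v, f in mapping.items():
        if f < 0:
            raise ConfigurationError(f"{name}[{v.value}] must be >= 0, got {f}")


#: Candidate parameter settings tested per strategy during the sweep, in the
#: order they are tried (used as the final tie-break).
PARAMETER_GRID: dict[str, list[StrategyParams]] = {
    "I": [
        IndividualizedThresholds(cdf_low=0.1, cdf_high=99.9),
        IndividualizedThresholds(cdf_low=0.5, cdf_high=99.5),
        IndividualizedThresholds(cdf_low=1.0, cdf_high=99.0),
    ],
    "II": [
        PostopElevation({Vital.HR: 0.05, Vital.RR: 0.05, Vital.TEMP: 0.01}),
        PostopElevation({Vital.HR: 0.10, Vital.RR: 0.10, Vital.TEMP: 0.025}),
        PostopElevation({Vital.HR: 0.25, Vital.RR: 0.25, Vital.TEMP: 0.05}),
    ],
    "III": [
        AnnunciationDelay(12),
        AnnunciationDelay(17),
        AnnunciationDelay(22),
    ],
    "IV": [
        DaytimeElevation({Vital.HR: 0.05, Vital.RR: 0.15}),
        DaytimeElevation({Vital.HR: 0.10, Vital.RR: 0.25}),
        DaytimeElevation({Vital.HR: 0.25, Vital.RR: 0.35}),
    ],
    "V": [
        NighttimeReduction({Vital.HR: 0.05, Vital.RR: 0.15}),
        NighttimeReduction({Vital.HR: 0.10, Vital.RR: 0.25}),
        NighttimeReduction({Vital.HR: 0.25, Vital.RR: 0.35}),
    ],
    "VI": [
        SlopeTrend(pd.Timedelta(hours=4)),
        SlopeTrend(pd.Timedelta(hours=8)),
        SlopeTrend(pd.Timedelta(hours=12)),
    ],
}


def optimal_params() -> dict[str, StrategyParams]:
    """Parameter settings found optimal per strategy in the original study."""
    return {
        "I": IndividualizedThresholds(cdf_low=1.0, cdf_high=99.0),
        "II": PostopElevation({Vital.HR: 0.05, Vital.RR: 0.05, Vital.TEMP: 0.01}),
        "III": AnnunciationDelay(12),
        "IV": DaytimeElevation({Vital.HR: 0.05, Vital.RR: 0.15}),
        "V": NighttimeReduction({Vital.HR: 0.10, Vital.RR: 0.25}),
        "VI": SlopeTrend(pd.Timedelta(hours=4)),
    }
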