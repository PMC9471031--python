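"""Per-breath metrics and exclusion rules.

Breaths carry two independent exclusion flags rather than being deleted:
a low-volume flag (integrated volume below the 90 mL noise floor) and a
spontaneous flag (instantaneous rate more than 30% away from the ventilator
set point).  Flags preserve the audit trail so summaries can report how many
breaths each rule removed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .processing import (
    FlowWaveform,
    ProcessingConfig,
    instantaneous_rate,
    integrate_volume,
    median_smooth,
    remove_instrument_noise,
    segment_breaths,
)


@dataclass
class Breath:
    onset: float  # s
    end: float  # s
    tidal_volume: float  # mL
    rate: float = math.nan  # breaths/min; NaN for the final breath
    excluded_low_volume: bool = False
    excluded_spontaneous: bool = False

    def __post_init__(self) -> None:
        if not self.end > self.onset:
            raise ValueError("breath end must follow onset")
        if self.tidal_volume < 0:
            raise ValueError("tidal_volume must be >= 0")

    @property
    def excluded(self) -> bool:
        return self.excluded_low_volume or self.excluded_spontaneous


@dataclass(frozen=True)
class BreathMetrics:
    """The four quantities summarised per anesthesia-record entry."""

    respiratory_rate: float  # breaths/min
    tidal_volume: float  # mL
    minute_ventilation: float  # L/min
    dynamic_compliance: float  # mL/cmH2O


def extract_breaths(wave: FlowWaveform, hysteresis_s: float = 0.025) -> list[Breath]:
    """Segment a conditioned waveform and compute per-breath tidal volume
    (trapezoidal integral over the interval) and instantaneous rate."""
    intervals = segment_breaths(wave, min_run_s=hysteresis_s)
    onsets = [a for a, _ in intervals]
    rates = instantaneous_rate(onsets) if len(onsets) >= 2 else np.empty(0)
    breaths = []
    for i, (a, b) in enumerate(intervals):
        tv = max(integrate_volume(wave, a, b), 0.0)
        r = float(rates[i]) if i < len(rates) else math.nan
        breaths.append(Breath(onset=a, end=b, tidal_volume=tv, rate=r))
    return breaths


def analyze_waveform(
    wave: FlowWaveform, config: ProcessingConfig = ProcessingConfig()
) -> list[Breath]:
    """The full chain in its fixed order: noise-floor zeroing, then median
    smoothing, then segmentation/integration.  Exclusion flags are left for
    the caller (the spontaneous rule needs the record's set rate)."""
    w = remove_instrument_noise(wave, config.noise_floor_flow)
    w = median_smooth(w, config.median_window)
    return extract_breaths(w, hysteresis_s=config.hysteresis_s)


def filter_low_volume(breaths: list[Breath], floor: float = 90.0) -> list[Breath]:
    """Flag breaths whose tidal volume is strictly below ``floor`` (mL).

    Breaths at exactly the floor are kept.  Nothing is deleted; re-running
    the filter is idempotent.
    """
    if not floor > 0:
        raise ValueError("floor must be > 0")
    for b in breaths:
        b.excluded_low_volume = b.tidal_volume < floor
    return breaths


def exclude_spontaneous(
    breaths: list[Breath], set_rr: float, tolerance: float = 0.30
) -> list[Breath]:
    """Flag breaths whose instantaneous rate deviates from the set rate by
    strictly more than ``tolerance`` (fractional).

    Breaths with an undefined rate (a patient's final breath) cannot deviate
    and are kept.  Idempotent.
    """
    if not set_rr > 0:
        raise ValueError("set_rr must be > 0")
    if not 0 < tolerance < 1:
        raise ValueError("tolerance must be in (0, 1)")
    for b in breaths:
        b.excluded_spontaneous = (
            math.isfinite(b.rate) and abs(b.rate - set_rr) / set_rr > tolerance
        )
    return breaths


def minute_ventilation(rate: float, tv: float) -> float:
    """Minute ventilation in L/min from rate (breaths/min) and TV (mL)."""
    if rate < 0 or tv < 0:
        raise ValueError("rate and tv must be >= 0")
    return rate * tv / 1000.0


def dynamic_compliance(tv: float, pip: float, peep: float) -> float:
    """Dynamic compliance TV/(PIP - PEEP) in mL/cmH2O."""
    if not pip > peep:
        raise ValueError(f"undefined compliance: PIP ({pip}) must exceed PEEP ({peep})")
    return tv / (pip - peep)
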