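"""Flow-waveform conditioning chain.

Raw expiratory/inspiratory-limb flow is processed in a fixed order: zero the
instrument-noise floor, smooth with a centred moving-median filter, then
integrate over breath intervals for tidal volume and difference breath-onset
times for instantaneous respiratory rate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd


@dataclass
class FlowWaveform:
    """Uniformly sampled flow-vs-time series for one patient limb.

    Attributes
    ----------
    time : ndarray
        Sample times in seconds, strictly increasing and uniform.
    flow : ndarray
        Flow in L/s; positive toward the patient.
    sample_rate : float
        Hz; must match the time spacing within 1 ppm.
    patient_id : str
    limb : str
        ``"inspiratory"`` or ``"expiratory"``.
    """

    time: np.ndarray
    flow: np.ndarray
    sample_rate: float
    patient_id: str = ""
    limb: str = "inspiratory"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        if self.time.shape != self.flow.shape or self.time.ndim != 1:
            raise ValueError("time and flow must be 1-D arrays of equal length")
        if len(self.time) >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise ValueError("time stamps must be strictly increasing")
            nominal = 1.0 / self.sample_rate
            if np.max(np.abs(dt - nominal)) > 1e-6 * nominal:
                raise ValueError("sample_rate inconsistent with time spacing")

    def __len__(self) -> int:
        return len(self.time)

    def with_flow(self, flow: np.ndarray) -> "FlowWaveform":
        return replace(self, time=self.time.copy(), flow=np.asarray(flow, float))


@dataclass(frozen=True)
class ProcessingConfig:
    """Analysis-chain constants.

    Defaults are the values used throughout: a 0.08 L/s instrument-noise
    floor, a 0.25 s moving-median window, a 90 mL integrated-volume floor and
    a 30% instantaneous-rate tolerance for spontaneous-breath exclusion.
    """

    noise_floor_flow: float = 0.08  # L/s
    median_window: float = 0.25  # s
    volume_floor: float = 90.0  # mL
    spontaneous_tolerance: float = 0.30  # fraction of set rate
    hysteresis_s: float = 0.025  # min run length for breath segmentation

    def __post_init__(self) -> None:
        for name in ("noise_floor_flow", "median_window", "volume_floor", "hysteresis_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.spontaneous_tolerance < 1:
            raise ValueError("spontaneous_tolerance must be in (0, 1)")


def remove_instrument_noise(wave: FlowWaveform, floor: float = 0.08) -> FlowWaveform:
    """Zero every sample with |flow| strictly below ``floor``.

    The floor is two-sided because expiratory flow is negative on the same
    transducer; samples at exactly the floor are retained.  Length and time
    base are preserved.
    """
    if len(wave) == 0:
        raise ValueError("empty waveform")
    if not floor > 0:
        raise ValueError("floor must be > 0")
    flow = np.where(np.abs(wave.flow) < floor, 0.0, wave.flow)
    return wave.with_flow(flow)


def median_smooth(wave: FlowWaveform, window: float = 0.25) -> FlowWaveform:
    """Centred moving-median filter of the given width in seconds.

    The window size in samples is ``round(window * sample_rate)`` forced odd
    so the centre sample is unambiguous.  At the series ends the window
    shrinks symmetrically (no padding: the filter never invents data), i.e.
    sample i uses the ``2*min(i, n-1-i, half)+1`` samples centred on i.
    """
    if len(wave) == 0:
        raise ValueError("empty waveform")
    if not window > 0:
        raise ValueError("window must be > 0")
    w = int(round(window * wave.sample_rate))
    if w % 2 == 0:
        w += 1
    if w < 3:
        raise ValueError(f"median window of {w} samples is shorter than 3")
    n = len(wave)
    half = w // 2
    x = wave.flow
    # interior: pandas rolling median (skip-list based, O(n log w))
    smoothed = (
        pd.Series(x).rolling(window=w, center=True, min_periods=w).median().to_numpy()
    )
    # symmetric shrinking windows at both ends
    n_edge = min(half, (n + 1) // 2)
    for i in range(n_edge):
        k = min(i, n - 1 - i)
        smoothed[i] = np.median(x[i - k : i + k + 1])
        j = n - 1 - i
        k = min(j, n - 1 - j)
        smoothed[j] = np.median(x[j - k : j + k + 1])
    if n <= w:  # whole series is "edge"
        for i in range(n):
            k = min(i, n - 1 - i, half)
            smoothed[i] = np.median(x[i - k : i + k + 1])
    return wave.with_flow(smoothed)


def integrate_volume(wave: FlowWaveform, t0: float, t1: float) -> float:
    """Trapezoidal integral of flow over [t0, t1], in mL (sign follows flow)."""
    if len(wave) == 0:
        raise ValueError("empty waveform")
    eps = 1e-9
    if not t0 < t1:
        raise ValueError("need t0 < t1")
    if t0 < wave.time[0] - eps or t1 > wave.time[-1] + eps:
        raise ValueError(
            f"[{t0}, {t1}] outside waveform span [{wave.time[0]}, {wave.time[-1]}]"
        )
    i0 = int(np.searchsorted(wave.time, t0 - eps, side="left"))
    i1 = int(np.searchsorted(wave.time, t1 + eps, side="right"))
    if i1 - i0 < 2:
        return 0.0
    return float(np.trapezoid(wave.flow[i0:i1], wave.time[i0:i1])) * 1000.0


def _run_lengths(mask: np.ndarray):
    """Run-length encode a boolean array as (value, start, length) triples."""
    if len(mask) == 0:
        return []
    change = np.flatnonzero(np.diff(mask.astype(np.int8))) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(mask)]))
    return [(bool(mask[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def segment_breaths(
    wave: FlowWaveform, min_run_s: float = 0.025
) -> list[tuple[float, float]]:
    """Breath intervals as (onset, end) times.

    A breath onset is the first sample of a run of positive flow following a
    run of non-positive flow; the interval ends at the last positive sample
    of the run.  Runs shorter than ``min_run_s`` (hysteresis) do not change
    state, suppressing chatter from residual noise at the zero crossings.
    Assumes the waveform has already been noise-floored and smoothed.
    """
    if len(wave) == 0:
        return []
    min_run = max(1, int(round(min_run_s * wave.sample_rate)))
    pos = wave.flow > 0
    runs = _run_lengths(pos)
    # debounce: short runs keep the current state
    state = runs[0][0] if runs[0][2] >= min_run else not runs[0][0]
    deb = np.empty(len(pos), dtype=bool)
    for value, start, length in runs:
        if length >= min_run:
            state = value
        deb[start : start + length] = state
    intervals = []
    for value, start, length in _run_lengths(deb):
        if value:
            onset = wave.time[start]
            end = wave.time[start + length - 1]
            if end > onset:
                intervals.append((float(onset), float(end)))
    return intervals


def instantaneous_rate(onsets) -> np.ndarray:
    """Instantaneous respiratory rate from breath-onset times.

    The first difference of the onset sequence gives inter-breath intervals;
    rate_i = 60 / (onset_{i+1} - onset_i) is assigned to breath i.  Fewer
    than two onsets yield an empty result.
    """
    onsets = np.asarray(onsets, dtype=float)
    if len(onsets) < 2:
        return np.empty(0)
    gaps = np.diff(onsets)
    if np.any(gaps <= 0):
        raise ValueError("onsets must be strictly increasing")
    return 60.0 / gaps
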