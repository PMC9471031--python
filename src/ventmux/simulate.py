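"""Synthetic split-circuit ventilation.

Generates per-patient flow and airway-pressure waveforms for a 1 + n(1)
ventilator-multiplexing circuit: one unrestricted "standard" patient and one
"variable" patient whose inspiratory limb carries a needle-valve flow
restrictor.  Each patient is a single-compartment linear lung (equation of
motion ``P = R*Q + V/C + PEEP``), the ventilator is either an ideal pressure
source (pressure control) or an ideal constant-flow source whose output is
divided between the branches (volume control).  Instrument noise and
patient-initiated (spontaneous) breaths can be superimposed afterwards so
that the downstream analysis chain has realistic artifacts to remove.

Units throughout: volume mL (internally L), flow L/s, pressure cmH2O,
compliance mL/cmH2O, resistance cmH2O/L/s, time s.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .processing import FlowWaveform

PRESSURE_CONTROL = "pressure_control"
VOLUME_CONTROL = "volume_control"

#: phase of the mechanical cycle (fraction of the breath period, from the
#: mechanical onset) at which an inserted spontaneous effort starts.  Placed
#: late in expiration so the effort is a separate positive-flow run whose
#: instantaneous rate (60 / gap-to-next-onset) deviates far more than 30%
#: from the set rate, while the preceding mechanical breath's rate stays
#: within tolerance.
SPONTANEOUS_PHASE = 0.8
SPONTANEOUS_DURATION_S = 0.4
SPONTANEOUS_TV_ML = 200.0

GROUND_TRUTH_COLUMNS = [
    "patient_id",
    "onset_s",
    "end_insp_s",
    "tv_mL",
    "rate_bpm",
    "spontaneous",
]


class ConfigError(ValueError):
    """Invalid circuit or ventilator configuration."""


@dataclass(frozen=True)
class LungModel:
    """Single-compartment lung.

    Parameters
    ----------
    compliance : float
        Static compliance C in mL/cmH2O.  Must be positive.
    resistance : float
        Airway (plus endotracheal tube) resistance R in cmH2O/L/s.
    """

    compliance: float
    resistance: float

    def __post_init__(self) -> None:
        if not self.compliance > 0:
            raise ConfigError(f"compliance must be > 0, got {self.compliance}")
        if self.resistance < 0:
            raise ConfigError(f"resistance must be >= 0, got {self.resistance}")

    @property
    def compliance_L(self) -> float:
        return self.compliance / 1000.0

    @property
    def time_constant(self) -> float:
        """R*C in seconds."""
        return self.resistance * self.compliance_L


@dataclass(frozen=True)
class ValveModel:
    """Needle-valve flow restrictor: handle turns -> pneumatic resistance.

    The handle travels from ``turns_full_closed`` (conventionally 0) to
    ``turns_full_open``.  Resistance falls strictly monotonically from
    ``r_closed`` at full closure to ``r_min`` at full open, by exponential
    interpolation; ``shape`` > 1 concentrates the change near closure, the
    steeply nonlinear behaviour characteristic of needle valves.  ``r_closed``
    is finite: even fully closed the valve passes some air, by design, to
    prevent unintentional hypoventilation of the restricted patient.
    """

    turns_full_open: float = 6.0
    turns_full_closed: float = 0.0
    r_min: float = 1.0
    r_closed: float = 200.0
    shape: float = 2.0

    def __post_init__(self) -> None:
        if not self.turns_full_open > self.turns_full_closed:
            raise ConfigError("turns_full_open must exceed turns_full_closed")
        if not (0 < self.r_min < self.r_closed):
            raise ConfigError("need 0 < r_min < r_closed")
        if not math.isfinite(self.r_closed):
            raise ConfigError("r_closed must be finite")
        if not self.shape > 0:
            raise ConfigError("shape must be > 0")


def valve_resistance(valve: ValveModel, turns_from_closed: float) -> float:
    """Resistance (cmH2O/L/s) of the valve at a handle position.

    ``turns_from_closed`` counts from full closure (0) up to
    ``valve.turns_full_open``.  Resistance is ``r_min * (r_closed/r_min) **
    x**shape`` with ``x`` the fractional closure, strictly decreasing in
    turns-from-closed and hitting both endpoints exactly.
    """
    lo, hi = valve.turns_full_closed, valve.turns_full_open
    if not lo <= turns_from_closed <= hi:
        raise ValueError(
            f"turns_from_closed={turns_from_closed} outside [{lo}, {hi}]"
        )
    x = 1.0 - (turns_from_closed - lo) / (hi - lo)  # 0 at open, 1 at closed
    return valve.r_min * (valve.r_closed / valve.r_min) ** (x**valve.shape)


@dataclass(frozen=True)
class VentilatorSettings:
    """Ventilator set points.

    ``rise_time`` is the first-order pressurization time constant of the
    inspiratory pressure source (a standard ventilator setting): the driving
    pressure approaches the target exponentially rather than as an ideal
    step, so inspiratory flow rises continuously from zero instead of
    jumping.  ``rise_time = 0`` gives the ideal square-wave drive and the
    textbook exponential flow response.
    """

    mode: str = PRESSURE_CONTROL
    set_pip: float = 25.0  # cmH2O, pressure-control target
    set_total_volume: float = 1200.0  # mL, volume-control total per breath
    peep: float = 5.0  # cmH2O
    set_rr: float = 12.0  # breaths/min
    inspiratory_fraction: float = 0.33  # Ti / breath period
    rise_time: float = 0.15  # s, pressure-control pressurization

    def __post_init__(self) -> None:
        if self.mode not in (PRESSURE_CONTROL, VOLUME_CONTROL):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if not self.set_rr > 0:
            raise ConfigError("set_rr must be > 0")
        if not 0 < self.inspiratory_fraction < 1:
            raise ConfigError("inspiratory_fraction must be in (0, 1)")
        if self.rise_time < 0:
            raise ConfigError("rise_time must be >= 0")
        if self.mode == PRESSURE_CONTROL and not self.set_pip > self.peep:
            raise ConfigError("set_pip must exceed peep in pressure control")
        if self.mode == VOLUME_CONTROL and not self.set_total_volume > 0:
            raise ConfigError("set_total_volume must be > 0 in volume control")

    @property
    def period(self) -> float:
        return 60.0 / self.set_rr

    @property
    def inspiratory_time(self) -> float:
        return self.period * self.inspiratory_fraction


@dataclass(frozen=True)
class CircuitConfig:
    """Full description of one simulated 1 + 1 split-ventilation run."""

    standard_lung: LungModel = field(
        default_factory=lambda: LungModel(compliance=20.0, resistance=10.0)
    )
    variable_lung: LungModel = field(
        default_factory=lambda: LungModel(compliance=50.0, resistance=10.0)
    )
    valve: ValveModel = field(default_factory=ValveModel)
    valve_turns: float = 6.0  # turns from closed; default fully open
    settings: VentilatorSettings = field(default_factory=VentilatorSettings)
    duration: float = 30.0  # s
    sample_rate: float = 2000.0  # Hz
    noise_sd: float = 0.02  # L/s
    spontaneous_breath_rate: float = 0.0  # events/min
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sample_rate > 0:
            raise ConfigError("sample_rate must be > 0")
        if not self.duration > 0:
            raise ConfigError("duration must be > 0")
        lo, hi = self.valve.turns_full_closed, self.valve.turns_full_open
        if not lo <= self.valve_turns <= hi:
            raise ConfigError(f"valve_turns must lie in [{lo}, {hi}]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.spontaneous_breath_rate < 0:
            raise ConfigError("spontaneous_breath_rate must be >= 0")


@dataclass
class WaveformSet:
    """Per-patient flow/pressure series on a shared time base plus a ground
    truth table (true per-breath tidal volumes, onsets, instantaneous rates
    and spontaneous labels) used by parameter-recovery tests."""

    time: np.ndarray
    flows: dict[str, np.ndarray]  # patient_id -> flow, L/s
    pressures: dict[str, np.ndarray]  # patient_id -> airway pressure, cmH2O
    ground_truth: pd.DataFrame
    sample_rate: float
    config: CircuitConfig | None = None

    def __post_init__(self) -> None:
        n = len(self.time)
        for pid, arr in {**self.flows, **self.pressures}.items():
            if len(arr) != n:
                raise ValueError(f"series for {pid!r} not on shared time base")
        if (self.ground_truth["tv_mL"] <= 0).any():
            raise ValueError("ground-truth tidal volumes must be positive")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.flows)

    def flow_waveform(self, patient_id: str) -> FlowWaveform:
        return FlowWaveform(
            time=self.time.copy(),
            flow=self.flows[patient_id].copy(),
            sample_rate=self.sample_rate,
            patient_id=patient_id,
        )

    def truth_for(self, patient_id: str) -> pd.DataFrame:
        gt = self.ground_truth
        return gt[gt["patient_id"] == patient_id].reset_index(drop=True)

    def copy(self) -> "WaveformSet":
        return WaveformSet(
            time=self.time.copy(),
            flows={k: v.copy() for k, v in self.flows.items()},
            pressures={k: v.copy() for k, v in self.pressures.items()},
            ground_truth=self.ground_truth.copy(),
            sample_rate=self.sample_rate,
            config=copy.deepcopy(self.config),
        )


# ---------------------------------------------------------------------------
# integration core


def _segment_euler(v0, m, drive, peep, r, c_L, dt):
    """Explicit-Euler solution of dV/dt = (drive - peep - V/C)/R over m
    fixed steps with a constant driving pressure.

    The recurrence V_{k+1} = a*V_k + b is affine with constant coefficients,
    so all m samples are produced vectorised.  Returns the per-sample flows
    Q_k = (drive - peep - V_k/C)/R, the per-sample volumes, and V_m.
    """
    if m <= 0:
        return np.empty(0), np.empty(0), v0
    a = 1.0 - dt / (r * c_L)
    b = dt * (drive - peep) / r
    k = np.arange(m)
    ak = a**k
    v = ak * v0 + b * (1.0 - ak) / (1.0 - a)
    q = (drive - peep - v / c_L) / r
    v_end = a**m * v0 + b * (1.0 - a**m) / (1.0 - a)
    return q, v, v_end


def _segment_euler_rise(v0, m, target, peep, r, c_L, dt, rise_time):
    """As `_segment_euler` but with a first-order pressurizing drive:
    dP/dt = (target - P)/rise_time starting from PEEP.  The volume recurrence
    V_{k+1} = a*V_k + f_k with time-varying forcing f_k is evaluated with an
    IIR filter (scipy.signal.lfilter), keeping the whole segment vectorised.
    """
    from scipy.signal import lfilter

    if rise_time <= 0:
        return _segment_euler(v0, m, target, peep, r, c_L, dt)
    if m <= 0:
        return np.empty(0), np.empty(0), v0
    a_p = 1.0 - dt / rise_time
    k = np.arange(m)
    drive = target - (target - peep) * a_p**k  # P_d at each sample
    a = 1.0 - dt / (r * c_L)
    f = dt * (drive - peep) / r
    y = lfilter([1.0], [1.0, -a], f)  # y[k] = a*y[k-1] + f[k]
    v = np.empty(m)
    v[0] = v0
    v[1:] = a ** k[1:] * v0 + y[:-1]
    q = (drive - peep - v / c_L) / r
    v_end = a**m * v0 + y[-1]
    return q, v, v_end


def _breath_grid(config: CircuitConfig):
    """Sample-index boundaries (onset, end-inspiration, end) of each complete
    breath that fits in the run."""
    fs = config.sample_rate
    n = int(round(config.duration * fs))
    t_period = config.settings.period
    ti = config.settings.inspiratory_time
    n_breaths = int(math.floor(config.duration / t_period + 1e-9))
    bounds = []
    for b in range(n_breaths):
        i0 = int(round(b * t_period * fs))
        i1 = int(round((b * t_period + ti) * fs))
        i2 = min(int(round((b + 1) * t_period * fs)), n)
        bounds.append((i0, i1, i2))
    return n, bounds


def _finish_ground_truth(rows: list[dict]) -> pd.DataFrame:
    """Assemble the truth table and assign instantaneous rates 60/(onset
    gap), NaN for each patient's final breath."""
    gt = pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS)
    out = []
    for pid, grp in gt.groupby("patient_id", sort=False):
        grp = grp.sort_values("onset_s").reset_index(drop=True)
        onsets = grp["onset_s"].to_numpy()
        rates = np.full(len(grp), np.nan)
        if len(onsets) > 1:
            rates[:-1] = 60.0 / np.diff(onsets)
        grp["rate_bpm"] = rates
        out.append(grp)
    return pd.concat(out, ignore_index=True) if out else gt


def _branch_resistances(config: CircuitConfig):
    """(inspiratory, expiratory) resistance per branch.  The restrictor sits
    on the variable patient's inspiratory limb only; one-way check valves
    route expiration around it."""
    r_valve = valve_resistance(config.valve, config.valve_turns)
    return {
        "standard": (config.standard_lung.resistance, config.standard_lung.resistance),
        "variable": (
            config.variable_lung.resistance + r_valve,
            config.variable_lung.resistance,
        ),
    }


def simulate_pressure_control(config: CircuitConfig) -> WaveformSet:
    """Noise-free pressure-control run.

    A shared pressure source drives each branch independently between PEEP
    and set PIP (pressurizing with ``settings.rise_time``; with zero rise
    time the drive is an ideal square wave and each branch is the textbook
    first-order RC step response).  Expiration is passive decay to PEEP.
    Closing the valve affects only the variable branch.
    """
    if config.settings.mode != PRESSURE_CONTROL:
        raise ConfigError("settings.mode must be pressure_control")
    s = config.settings
    dt = 1.0 / config.sample_rate
    n, bounds = _breath_grid(config)
    time = np.arange(n) * dt
    res = _branch_resistances(config)
    lungs = {"standard": config.standard_lung, "variable": config.variable_lung}
    r_valve = valve_resistance(config.valve, config.valve_turns)

    flows, pressures, rows = {}, {}, []
    for pid, lung in lungs.items():
        r_in, r_ex = res[pid]
        c_L = lung.compliance_L
        flow = np.zeros(n)
        pres = np.full(n, s.peep)
        v = 0.0
        for i0, i1, i2 in bounds:
            v_start = v
            m = i1 - i0
            q, vv, v = _segment_euler_rise(
                v, m, s.set_pip, s.peep, r_in, c_L, dt, s.rise_time
            )
            flow[i0:i1] = q
            # pressure at the patient wye, distal to the restrictor
            rv = r_valve if pid == "variable" else 0.0
            drive = vv / c_L + q * r_in + s.peep  # source pressure this step
            pres[i0:i1] = drive - rv * q
            rows.append(
                dict(
                    patient_id=pid,
                    onset_s=i0 * dt,
                    end_insp_s=i1 * dt,
                    tv_mL=(v - v_start) * 1000.0,
                    rate_bpm=np.nan,
                    spontaneous=False,
                )
            )
            q, _, v = _segment_euler(v, i2 - i1, s.peep, s.peep, r_ex, c_L, dt)
            flow[i1:i2] = q
        flows[pid] = flow
        pressures[pid] = pres

    return WaveformSet(
        time=time,
        flows=flows,
        pressures=pressures,
        ground_truth=_finish_ground_truth(rows),
        sample_rate=config.sample_rate,
        config=config,
    )


def simulate_volume_control(config: CircuitConfig) -> WaveformSet:
    """Noise-free volume-control run.

    The ventilator delivers ``set_total_volume`` per breath as a constant
    total inspiratory flow; at every time step the flow divides between the
    branches in inverse proportion to instantaneous branch impedance
    (inspiratory resistance plus elastic back-pressure V/C), so restricting
    the variable branch shifts volume to the standard branch.  One-way check
    valves clamp branch flow at zero (no retrograde flow).
    """
    if config.settings.mode != VOLUME_CONTROL:
        raise ConfigError("settings.mode must be volume_control")
    s = config.settings
    dt = 1.0 / config.sample_rate
    n, bounds = _breath_grid(config)
    time = np.arange(n) * dt
    res = _branch_resistances(config)
    q_tot = (s.set_total_volume / 1000.0) / s.inspiratory_time
    r_valve = valve_resistance(config.valve, config.valve_turns)

    c_std = config.standard_lung.compliance_L
    c_var = config.variable_lung.compliance_L
    r_std_in, r_std_ex = res["standard"]
    r_var_in, r_var_ex = res["variable"]

    flow_s, flow_v = np.zeros(n), np.zeros(n)
    pres_s, pres_v = np.full(n, s.peep), np.full(n, s.peep)
    rows = []
    v_s = v_v = 0.0
    g_s, g_v = 1.0 / r_std_in, 1.0 / r_var_in
    for i0, i1, i2 in bounds:
        v_s0, v_v0 = v_s, v_v
        for j in range(i0, i1):
            e_s, e_v = v_s / c_std, v_v / c_var
            p_node = s.peep + (q_tot + e_s * g_s + e_v * g_v) / (g_s + g_v)
            q_s = (p_node - s.peep - e_s) * g_s
            q_v = (p_node - s.peep - e_v) * g_v
            if q_s < 0.0:  # check valve: all flow to the variable branch
                q_s, q_v = 0.0, q_tot
                p_node = s.peep + e_v + q_v * r_var_in
            elif q_v < 0.0:
                q_s, q_v = q_tot, 0.0
                p_node = s.peep + e_s + q_s * r_std_in
            flow_s[j], flow_v[j] = q_s, q_v
            pres_s[j] = p_node
            pres_v[j] = p_node - r_valve * q_v
            v_s += q_s * dt
            v_v += q_v * dt
        for pid, v0, v_now in (
            ("standard", v_s0, v_s),
            ("variable", v_v0, v_v),
        ):
            rows.append(
                dict(
                    patient_id=pid,
                    onset_s=i0 * dt,
                    end_insp_s=i1 * dt,
                    tv_mL=(v_now - v0) * 1000.0,
                    rate_bpm=np.nan,
                    spontaneous=False,
                )
            )
        q, _, v_s = _segment_euler(v_s, i2 - i1, s.peep, s.peep, r_std_ex, c_std, dt)
        flow_s[i1:i2] = q
        q, _, v_v = _segment_euler(v_v, i2 - i1, s.peep, s.peep, r_var_ex, c_var, dt)
        flow_v[i1:i2] = q

    return WaveformSet(
        time=time,
        flows={"standard": flow_s, "variable": flow_v},
        pressures={"standard": pres_s, "variable": pres_v},
        ground_truth=_finish_ground_truth(rows),
        sample_rate=config.sample_rate,
        config=config,
    )


def add_instrument_artifacts(
    waves: WaveformSet,
    noise_sd: float,
    spontaneous_rate: float,
    seed: int,
) -> WaveformSet:
    """Superimpose the two artifact classes the analysis chain must remove:
    zero-mean Gaussian transducer noise, and spontaneous (patient-initiated)
    breaths inserted late in randomly chosen expiratory phases.

    Inserted efforts are half-sine flow pulses labelled ``spontaneous`` in
    the ground truth; by construction their instantaneous rate deviates from
    the set rate by more than 30% while neighbouring mechanical breaths stay
    within tolerance.  Reproducible for a fixed seed; with ``noise_sd == 0``
    and ``spontaneous_rate == 0`` the output equals the input.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if spontaneous_rate < 0:
        raise ValueError("spontaneous_rate must be >= 0")
    out = waves.copy()
    if noise_sd == 0 and spontaneous_rate == 0:
        return out

    rng = np.random.default_rng(seed)
    fs = out.sample_rate
    n = len(out.time)

    if spontaneous_rate > 0:
        if out.config is None:
            raise ValueError("spontaneous insertion needs waves.config.settings")
        t_period = out.config.settings.period
        duration = n / fs
        new_rows = []
        for pid in out.patient_ids:
            truth = out.truth_for(pid)
            mech = truth[~truth["spontaneous"]]
            onsets = mech["onset_s"].to_numpy()
            eligible = np.arange(max(len(onsets) - 1, 0))
            n_events = min(len(eligible), int(round(spontaneous_rate * duration / 60.0)))
            if n_events == 0:
                continue
            chosen = rng.choice(eligible, size=n_events, replace=False)
            amp = (SPONTANEOUS_TV_ML / 1000.0) * math.pi / (2.0 * SPONTANEOUS_DURATION_S)
            for b in np.sort(chosen):
                t_on = onsets[b] + SPONTANEOUS_PHASE * t_period
                i_on = int(round(t_on * fs))
                i_off = min(int(round((t_on + SPONTANEOUS_DURATION_S) * fs)), n)
                tt = out.time[i_on:i_off] - t_on
                out.flows[pid][i_on:i_off] += amp * np.sin(
                    math.pi * tt / SPONTANEOUS_DURATION_S
                )
                new_rows.append(
                    dict(
                        patient_id=pid,
                        onset_s=t_on,
                        end_insp_s=t_on + SPONTANEOUS_DURATION_S,
                        tv_mL=SPONTANEOUS_TV_ML,
                        rate_bpm=np.nan,
                        spontaneous=True,
                    )
                )
        if new_rows:
            merged = pd.concat(
                [out.ground_truth, pd.DataFrame(new_rows)], ignore_index=True
            )
            out.ground_truth = _finish_ground_truth(merged.to_dict("records"))

    if noise_sd > 0:
        for pid in out.patient_ids:
            out.flows[pid] = out.flows[pid] + rng.normal(0.0, noise_sd, n)

    return out


def simulate(config: CircuitConfig) -> WaveformSet:
    """Run the configured mode and apply the configured artifacts."""
    if config.settings.mode == PRESSURE_CONTROL:
        ws = simulate_pressure_control(config)
    else:
        ws = simulate_volume_control(config)
    return add_instrument_artifacts(
        ws, config.noise_sd, config.spontaneous_breath_rate, config.seed
    )
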