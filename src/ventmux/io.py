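"""CSV/YAML plumbing between the pipeline stages."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .breaths import Breath
from .processing import FlowWaveform, ProcessingConfig
from .simulate import (
    CircuitConfig,
    LungModel,
    ValveModel,
    VentilatorSettings,
    WaveformSet,
)

WAVE_COLUMNS = ["time_s", "flow_Lps", "pressure_cmH2O", "patient_id"]
BREATH_COLUMNS = [
    "patient_id",
    "onset_s",
    "end_s",
    "tv_mL",
    "rate_bpm",
    "excluded_low_volume",
    "excluded_spontaneous",
]


def write_waveforms_csv(waves: WaveformSet, path) -> None:
    frames = [
        pd.DataFrame(
            {
                "time_s": waves.time,
                "flow_Lps": waves.flows[pid],
                "pressure_cmH2O": waves.pressures[pid],
                "patient_id": pid,
            }
        )
        for pid in waves.patient_ids
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_ground_truth_csv(waves: WaveformSet, path) -> None:
    waves.ground_truth.to_csv(path, index=False)


def read_waveforms_csv(path) -> dict[str, FlowWaveform]:
    """Read a long-format waveform CSV into one FlowWaveform per patient.

    Requires time_s, flow_Lps and patient_id columns; the sample rate is
    inferred from the median time step.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("time_s", "flow_Lps", "patient_id") if c not in df.columns]
    if missing:
        raise ValueError(f"waveform CSV missing columns: {missing}")
    if len(df) == 0:
        raise ValueError("waveform CSV is empty")
    out = {}
    for pid, grp in df.groupby("patient_id", sort=False):
        t = grp["time_s"].to_numpy(float)
        fs = 1.0 / float(np.median(np.diff(t)))
        out[str(pid)] = FlowWaveform(
            time=t, flow=grp["flow_Lps"].to_numpy(float), sample_rate=fs,
            patient_id=str(pid),
        )
    return out


def breaths_to_frame(breaths: list[Breath], patient_id: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": patient_id,
                "onset_s": b.onset,
                "end_s": b.end,
                "tv_mL": b.tidal_volume,
                "rate_bpm": b.rate,
                "excluded_low_volume": b.excluded_low_volume,
                "excluded_spontaneous": b.excluded_spontaneous,
            }
            for b in breaths
        ],
        columns=BREATH_COLUMNS,
    )


# --- configuration -------------------------------------------------------


def circuit_config_to_dict(config: CircuitConfig) -> dict:
    return {
        "standard_lung": {
            "compliance": config.standard_lung.compliance,
            "resistance": config.standard_lung.resistance,
        },
        "variable_lung": {
            "compliance": config.variable_lung.compliance,
            "resistance": config.variable_lung.resistance,
        },
        "valve": {
            "turns_full_open": config.valve.turns_full_open,
            "turns_full_closed": config.valve.turns_full_closed,
            "r_min": config.valve.r_min,
            "r_closed": config.valve.r_closed,
            "shape": config.valve.shape,
        },
        "valve_turns": config.valve_turns,
        "settings": {
            "mode": config.settings.mode,
            "set_pip": config.settings.set_pip,
            "set_total_volume": config.settings.set_total_volume,
            "peep": config.settings.peep,
            "set_rr": config.settings.set_rr,
            "inspiratory_fraction": config.settings.inspiratory_fraction,
        },
        "duration": config.duration,
        "sample_rate": config.sample_rate,
        "noise_sd": config.noise_sd,
        "spontaneous_breath_rate": config.spontaneous_breath_rate,
        "seed": config.seed,
    }


def circuit_config_from_dict(d: dict) -> CircuitConfig:
    kwargs = dict(d)
    if "standard_lung" in kwargs:
        kwargs["standard_lung"] = LungModel(**kwargs["standard_lung"])
    if "variable_lung" in kwargs:
        kwargs["variable_lung"] = LungModel(**kwargs["variable_lung"])
    if "valve" in kwargs:
        kwargs["valve"] = ValveModel(**kwargs["valve"])
    if "settings" in kwargs:
        kwargs["settings"] = VentilatorSettings(**kwargs["settings"])
    return CircuitConfig(**kwargs)


def load_circuit_config(path) -> CircuitConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return circuit_config_from_dict(data or {})


def save_circuit_config(config: CircuitConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(circuit_config_to_dict(config), fh, sort_keys=False)


def processing_config_from_dict(d: dict) -> ProcessingConfig:
    return ProcessingConfig(**d)
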