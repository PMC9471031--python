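"""Anesthesia-record alignment and per-entry summaries.

Each anesthesia-record entry opens a half-open time window [t_k, t_{k+1})
(the final entry extends to the end of the recording).  Breaths are assigned
to the window containing their onset; per-entry means and sample standard
deviations of respiratory rate, tidal volume, minute ventilation and dynamic
compliance are computed over non-excluded breaths only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .breaths import Breath, dynamic_compliance, exclude_spontaneous, filter_low_volume, minute_ventilation

RECORD_COLUMNS = [
    "timestamp_s",
    "set_rr",
    "set_total_volume_mL",
    "pip_cmH2O",
    "peep_cmH2O",
    "mean_pressure_cmH2O",
    "valve_turns_from_closed",
    "mode",
]


@dataclass
class AnesthesiaRecord:
    """Ordered timestamped ventilator settings / valve positions."""

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in RECORD_COLUMNS if c not in self.entries.columns]
        if missing:
            raise ValueError(f"anesthesia record missing columns: {missing}")
        ts = self.entries["timestamp_s"].to_numpy(float)
        if len(ts) == 0:
            raise ValueError("anesthesia record has no entries")
        if np.any(np.diff(ts) <= 0):
            raise ValueError("record timestamps must be strictly increasing")
        self.entries = self.entries.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_csv(cls, path) -> "AnesthesiaRecord":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)


def record_from_config(config, timestamp: float = 0.0) -> AnesthesiaRecord:
    """Single-entry anesthesia record mirroring a simulation config — the
    record a clinician would chart for one steady period of the run."""
    s = config.settings
    return AnesthesiaRecord(
        pd.DataFrame(
            [
                {
                    "timestamp_s": timestamp,
                    "set_rr": s.set_rr,
                    "set_total_volume_mL": s.set_total_volume,
                    "pip_cmH2O": s.set_pip,
                    "peep_cmH2O": s.peep,
                    "mean_pressure_cmH2O": math.nan,
                    "valve_turns_from_closed": config.valve_turns,
                    "mode": s.mode,
                }
            ]
        )
    )


def align(
    breaths: list[Breath], record: AnesthesiaRecord
) -> tuple[dict[int, list[Breath]], list[Breath]]:
    """Assign each breath to the record entry whose window contains its onset.

    Returns (entry index -> breaths, unassigned).  Breaths whose onset
    precedes the first entry are unassigned; an onset exactly at an entry
    timestamp belongs to that entry (half-open windows).
    """
    ts = record.entries["timestamp_s"].to_numpy(float)
    mapping: dict[int, list[Breath]] = {k: [] for k in range(len(ts))}
    unassigned: list[Breath] = []
    for b in breaths:
        k = int(np.searchsorted(ts, b.onset, side="right")) - 1
        if k < 0:
            unassigned.append(b)
        else:
            mapping[k].append(b)
    return mapping, unassigned


def apply_exclusions(
    mapping: dict[int, list[Breath]],
    record: AnesthesiaRecord,
    volume_floor: float = 90.0,
    tolerance: float = 0.30,
) -> dict[int, list[Breath]]:
    """Run both exclusion rules entry-by-entry, taking each window's set
    respiratory rate from the record."""
    for k, breaths in mapping.items():
        if not breaths:
            continue
        set_rr = float(record.entries.loc[k, "set_rr"])
        if not math.isfinite(set_rr) or set_rr <= 0:
            raise ValueError(
                f"entry {k} has no usable set_rr for breath at "
                f"{breaths[0].onset:.3f} s"
            )
        filter_low_volume(breaths, volume_floor)
        exclude_spontaneous(breaths, set_rr, tolerance)
    return mapping


def summarize(
    mapping: dict[int, list[Breath]], record: AnesthesiaRecord
) -> pd.DataFrame:
    """Per-entry mean and sample (n-1) SD of rate, tidal volume, minute
    ventilation and dynamic compliance over non-excluded breaths.

    SDs are NaN when fewer than two breaths remain; all statistics are NaN
    for empty entries.  Dynamic compliance uses the entry's PIP and PEEP.
    """
    rows = []
    for k in range(len(record)):
        entry = record.entries.loc[k]
        breaths = mapping.get(k, [])
        kept = [b for b in breaths if not b.excluded]
        pip, peep = float(entry["pip_cmH2O"]), float(entry["peep_cmH2O"])
        tv = np.array([b.tidal_volume for b in kept])
        rr = np.array([b.rate for b in kept])
        rr = rr[np.isfinite(rr)]
        mv = np.array(
            [minute_ventilation(b.rate, b.tidal_volume) for b in kept if math.isfinite(b.rate)]
        )
        if pip > peep:
            cd = np.array([dynamic_compliance(b.tidal_volume, pip, peep) for b in kept])
        else:
            cd = np.empty(0)

        def _mean(x):
            return float(np.mean(x)) if len(x) else math.nan

        def _sd(x):
            return float(np.std(x, ddof=1)) if len(x) >= 2 else math.nan

        rows.append(
            {
                "entry_index": k,
                "timestamp_s": float(entry["timestamp_s"]),
                "n_breaths": len(kept),
                "n_excluded": sum(b.excluded for b in breaths),
                "rr_mean_bpm": _mean(rr),
                "rr_sd_bpm": _sd(rr),
                "tv_mean_mL": _mean(tv),
                "tv_sd_mL": _sd(tv),
                "mv_mean_Lpm": _mean(mv),
                "mv_sd_Lpm": _sd(mv),
                "cdyn_mean_mL_per_cmH2O": _mean(cd),
                "cdyn_sd_mL_per_cmH2O": _sd(cd),
            }
        )
    return pd.DataFrame(rows)


def percent_of_set_tv(mean_tv: float, set_total_volume: float) -> float:
    """Measured mean tidal volume as a percent of the currently set
    ventilator volume; values above 100 are permitted."""
    if not set_total_volume > 0:
        raise ValueError("set_total_volume must be > 0")
    return 100.0 * mean_tv / set_total_volume


def tv_ratio(standard_tv: float, variable_tv: float) -> float:
    """Standard-patient over variable-patient tidal volume."""
    if not variable_tv > 0:
        raise ValueError("variable_tv must be > 0")
    return standard_tv / variable_tv
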