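"""Bench calibration of the flow restrictor.

A calibration sweep records tidal volume and pressures at successive valve
handle positions.  Two turn conventions appear in practice and both are
supported explicitly: bench tables count turns *from open* (0 = fully open),
in-vivo records count turns *from closed* (0 = fully closed, full travel =
fully open).  Normalisation expresses every quantity as a percent of its
value at the fully-open position of the same curve.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

TURNS_FROM_OPEN = "turns_from_open"
TURNS_FROM_CLOSED = "turns_from_closed"

CURVE_COLUMNS = ["handle_position", "tv_mL", "pip_cmH2O", "peep_cmH2O"]


@dataclass
class CalibrationCurve:
    points: pd.DataFrame  # columns CURVE_COLUMNS, positions strictly monotone
    convention: str = TURNS_FROM_OPEN
    total_travel_turns: float = 6.0

    def __post_init__(self) -> None:
        missing = [c for c in CURVE_COLUMNS if c not in self.points.columns]
        if missing:
            raise ValueError(f"calibration table missing columns: {missing}")
        if self.convention not in (TURNS_FROM_OPEN, TURNS_FROM_CLOSED):
            raise ValueError(f"unknown convention {self.convention!r}")
        if not self.total_travel_turns > 0:
            raise ValueError("total_travel_turns must be > 0")
        pos = self.points["handle_position"].to_numpy(float)
        if len(pos) == 0:
            raise ValueError("calibration table is empty")
        d = np.diff(pos)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("handle positions must be strictly monotone")
        self.points = self.points.reset_index(drop=True)

    @property
    def open_position(self) -> float:
        return 0.0 if self.convention == TURNS_FROM_OPEN else self.total_travel_turns

    def _open_row(self) -> pd.Series:
        pos = self.points["handle_position"].to_numpy(float)
        hit = np.isclose(pos, self.open_position, atol=1e-9)
        if not hit.any():
            raise ValueError(
                f"no point at the fully-open position ({self.open_position} "
                f"{self.convention})"
            )
        return self.points.iloc[int(np.flatnonzero(hit)[0])]

    def turns_from_open(self, position: float) -> float:
        """Handle travel from fully open, in turns, for a position given in
        this curve's convention."""
        if self.convention == TURNS_FROM_OPEN:
            return position
        return self.total_travel_turns - position

    def to_convention(self, convention: str) -> "CalibrationCurve":
        if convention == self.convention:
            return replace(self, points=self.points.copy())
        pts = self.points.copy()
        pts["handle_position"] = self.total_travel_turns - pts["handle_position"]
        return CalibrationCurve(
            points=pts.iloc[::-1].reset_index(drop=True),
            convention=convention,
            total_travel_turns=self.total_travel_turns,
        )


@dataclass(frozen=True)
class ControlRange:
    """Usable handle travel: from the first position where delivery departs
    from the fully-open value to full closure, in turns from open."""

    onset_turns: float
    closed_turns: float

    def __post_init__(self) -> None:
        if self.closed_turns < self.onset_turns:
            raise ValueError("closed_turns must be >= onset_turns")

    @property
    def width(self) -> float:
        return self.closed_turns - self.onset_turns


def normalize_to_open(curve: CalibrationCurve) -> CalibrationCurve:
    """Express tidal volume and pressures as percent of their fully-open
    values (same patient, same quantity).

    The open position maps to 100% in every column; values above 100% are
    legitimate (the unrestricted patient can gain delivery as the other
    branch closes).  Idempotent: normalising twice is a no-op.  Columns
    whose open value is zero (e.g. a zero-PEEP sweep) become NaN.
    """
    open_row = curve._open_row()
    if not open_row["tv_mL"] > 0:
        raise ValueError("fully-open tidal volume must be > 0")
    pts = curve.points.copy()
    for col in ("tv_mL", "pip_cmH2O", "peep_cmH2O"):
        ref = float(open_row[col])
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = 100.0 * pts[col].to_numpy(float) / ref
        pts[col] = np.where(np.isfinite(vals), vals, np.nan)
    return replace(curve, points=pts)


def closure_percent(position: float, curve: CalibrationCurve) -> float:
    """Handle position as percent closure: 0% fully open, 100% fully closed."""
    traveled = curve.turns_from_open(position)
    if not -1e-9 <= traveled <= curve.total_travel_turns + 1e-9:
        raise ValueError(
            f"position {position} outside the valve's travel "
            f"[0, {curve.total_travel_turns}] turns from open"
        )
    return 100.0 * traveled / curve.total_travel_turns


def control_range(onset_turns: float, closed_turns: float) -> ControlRange:
    """Control range from its endpoints, in turns from open."""
    if closed_turns < onset_turns:
        raise ValueError("closed_turns must be >= onset_turns")
    return ControlRange(onset_turns=onset_turns, closed_turns=closed_turns)


def detect_control_range(
    normalized: CalibrationCurve, rel_tol: float = 0.01
) -> ControlRange:
    """Find the control range on a normalised sweep: the onset is the first
    position (in turns from open) where tidal volume departs from 100% by
    more than ``rel_tol`` (fractional); full closure is the sweep's last
    position.  A sweep that never departs has zero width."""
    pts = normalized.points
    travel = np.array(
        [normalized.turns_from_open(p) for p in pts["handle_position"].to_numpy(float)]
    )
    order = np.argsort(travel)
    travel = travel[order]
    tv = pts["tv_mL"].to_numpy(float)[order]
    closed = float(travel[-1])
    departed = np.abs(tv - 100.0) > 100.0 * rel_tol
    if departed.any():
        onset = float(travel[int(np.flatnonzero(departed)[0])])
    else:
        onset = closed
    return ControlRange(onset_turns=onset, closed_turns=closed)
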