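"""Force-plate kinetics: center-of-pressure traces and stance criteria.

The force plate is four footplates, each on a uniaxial load cell, one under
each paw: front-left (FL), front-right (FR), hind-left (HL), hind-right
(HR).  The center-of-pressure (CoP) signals are mass-normalized force
differences between plate halves,

    CoP_lat = ((F_FL + F_HL) - (F_FR + F_HR)) / m
    CoP_ap  = ((F_FL + F_FR) - (F_HL + F_HR)) / m

in N/kg (plate geometry is not used, so these are not metric positions).
The fore-aft expression is parenthesized as (front sum) - (hind sum),
mirroring the structure of the lateral one.

Stance symmetry at trial start requires weight balanced across halves
(< 10 N front-hind and left-right difference) and a level, forward-facing
head (< 10 deg deviation on every axis); all thresholds are strict.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import butter, filtfilt

__all__ = [
    "ForcePlateTrace",
    "CoPTrace",
    "StanceCheck",
    "compute_cop",
    "stance_check",
    "STANCE_FORCE_THRESHOLD_N",
    "STANCE_HEAD_THRESHOLD_DEG",
]

STANCE_FORCE_THRESHOLD_N = 10.0
STANCE_HEAD_THRESHOLD_DEG = 10.0


@dataclass(frozen=True)
class ForcePlateTrace:
    """Vertical force per footplate (N) on a uniform time grid, plus mass (kg)."""

    time: np.ndarray
    F_FL: np.ndarray
    F_FR: np.ndarray
    F_HL: np.ndarray
    F_HR: np.ndarray
    mass: float

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("F_FL", "F_FR", "F_HL", "F_HR"):
            arr = getattr(self, name)
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != time length {n}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        if not self.mass > 0:
            raise ValueError(f"mass must be > 0, got {self.mass}")


@dataclass(frozen=True)
class CoPTrace:
    """Lateral and fore-aft CoP (N/kg) on the force trace's grid."""

    time: np.ndarray
    lat: np.ndarray
    ap: np.ndarray

    def channel(self, axis: str) -> np.ndarray:
        """CoP component along a perturbation axis (roll -> lat, pitch -> ap)."""
        return self.lat if axis == "roll" else self.ap


def compute_cop(
    forces: ForcePlateTrace, lowpass_hz: float | None = None
) -> CoPTrace:
    """Mass-normalized CoP from the four footplate forces.

    ``lowpass_hz`` optionally applies a zero-phase 4th-order Butterworth
    low-pass to the force channels first; default is no filtering.
    """
    f = [forces.F_FL, forces.F_FR, forces.F_HL, forces.F_HR]
    if lowpass_hz is not None:
        fs = 1.0 / float(np.mean(np.diff(forces.time)))
        b, a = butter(4, lowpass_hz, fs=fs)
        f = [filtfilt(b, a, x) for x in f]
    ffl, ffr, fhl, fhr = f
    lat = ((ffl + fhl) - (ffr + fhr)) / forces.mass
    ap = ((ffl + ffr) - (fhl + fhr)) / forces.mass
    return CoPTrace(time=forces.time, lat=lat, ap=ap)


@dataclass(frozen=True)
class StanceCheck:
    """Per-criterion trial-start stance booleans."""

    fore_aft_ok: bool  # |front - hind| < 10 N
    left_right_ok: bool  # |left - right| < 10 N
    head_ok: bool  # every head-axis deviation < 10 deg

    @property
    def ok(self) -> bool:
        return self.fore_aft_ok and self.left_right_ok and self.head_ok


def stance_check(
    forces_at_start: Sequence[float],
    head_orientation_deg: Sequence[float],
    force_threshold: float = STANCE_FORCE_THRESHOLD_N,
    head_threshold: float = STANCE_HEAD_THRESHOLD_DEG,
) -> StanceCheck:
    """Evaluate the trial-start stance-symmetry criteria at one time sample.

    ``forces_at_start`` is (F_FL, F_FR, F_HL, F_HR) in N;
    ``head_orientation_deg`` the head deviation from level/straight-ahead
    per axis.  All comparisons are strict inequalities.
    """
    ffl, ffr, fhl, fhr = (float(x) for x in forces_at_start)
    front_hind = abs((ffl + ffr) - (fhl + fhr))
    left_right = abs((ffl + fhl) - (ffr + fhr))
    head_dev = np.abs(np.asarray(head_orientation_deg, dtype=float))
    return StanceCheck(
        fore_aft_ok=front_hind < force_threshold,
        left_right_ok=left_right < force_threshold,
        head_ok=bool(np.all(head_dev < head_threshold)),
    )
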