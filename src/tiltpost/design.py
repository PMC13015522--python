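"""Perturbation waveform design.

Rotational support-surface perturbations are specified by three kinematic
parameters that this module keeps independent: peak angular acceleration A
(deg/s^2), peak angular velocity V (deg/s), and total angular displacement D
(deg).  The platform command is a trapezoidal velocity profile built from a
piecewise-constant acceleration signal:

    +A  for d1 = V / A            (acceleration block)
     0  for d2 = (D - V^2/A) / V  (constant-velocity plateau)
    -A  for d1                    (mirrored deceleration block)

The profile is constructed in continuous time with exact block durations,
integrated analytically (velocity piecewise linear, position piecewise
quadratic) and sampled on the platform command grid.  This preserves the
total displacement exactly even when the block durations are not multiples
of the command period.  A grid-quantized variant, in which block durations
are rounded to the command grid before integration, is available for
fidelity studies of a real platform's discrete-time command stream.

Feasibility: the trapezoid can only reach V within the displacement budget
when V^2/A <= D; the d2 = 0 boundary is the pure triangular profile.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "Axis",
    "Direction",
    "PerturbationSpec",
    "Waveform",
    "ProtocolConfig",
    "ValidationReport",
    "InfeasibleSpecError",
    "design_waveform",
    "enumerate_conditions",
    "validate_waveform",
    "STUDY_PROTOCOL",
]

# Axis/direction vocabulary.  Pitch is rotation about the interaural axis
# (forward/backward tilt), roll about the naso-occipital axis (left/right).
Axis = str
Direction = str

_AXIS_DIRECTIONS: dict[str, tuple[str, str]] = {
    "pitch": ("forward", "backward"),
    "roll": ("leftward", "rightward"),
}

# Sign convention (centralized here; all downstream sign handling refers to
# this map): forward pitch and leftward roll are positive.
DIRECTION_SIGN: dict[str, int] = {
    "forward": +1,
    "backward": -1,
    "leftward": +1,
    "rightward": -1,
}


class InfeasibleSpecError(ValueError):
    """Raised when a perturbation spec cannot be realized as a trapezoid."""


@dataclass(frozen=True)
class PerturbationSpec:
    """One perturbation condition.

    Parameters
    ----------
    axis : {"pitch", "roll"}
    direction : {"forward", "backward"} for pitch, {"leftward", "rightward"} for roll
    peak_accel : float
        Acceleration-block amplitude A, deg/s^2 (> 0).
    peak_vel : float
        Plateau velocity V, deg/s (> 0).
    displacement : float
        Total platform angle D, deg (> 0); requires V^2/A <= D.
    command_rate : float
        Platform command grid, samples/s.
    """

    axis: Axis
    direction: Direction
    peak_accel: float
    peak_vel: float
    displacement: float
    command_rate: float = 100.0

    def __post_init__(self) -> None:
        if self.axis not in _AXIS_DIRECTIONS:
            raise ValueError(f"unknown axis {self.axis!r}")
        if self.direction not in _AXIS_DIRECTIONS[self.axis]:
            raise ValueError(
                f"direction {self.direction!r} is not compatible with axis {self.axis!r}"
            )
        for name in ("peak_accel", "peak_vel", "displacement", "command_rate"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.peak_vel**2 / self.peak_accel > self.displacement * (1 + 1e-12):
            raise InfeasibleSpecError(
                "peak_vel^2 / peak_accel = "
                f"{self.peak_vel**2 / self.peak_accel:g} deg exceeds displacement "
                f"{self.displacement:g} deg: the trapezoid cannot reach peak_vel "
                "within the displacement budget"
            )

    @property
    def sign(self) -> int:
        return DIRECTION_SIGN[self.direction]

    @property
    def accel_duration(self) -> float:
        """Duration d1 of each acceleration/deceleration block, s."""
        return self.peak_vel / self.peak_accel

    @property
    def plateau_duration(self) -> float:
        """Duration d2 of the constant-velocity plateau, s (0 for triangular)."""
        d2 = (self.displacement - self.peak_vel**2 / self.peak_accel) / self.peak_vel
        return max(d2, 0.0)

    @property
    def motion_duration(self) -> float:
        """Total platform motion time 2*d1 + d2, s."""
        return 2.0 * self.accel_duration + self.plateau_duration

    @property
    def profile_key(self) -> tuple[float, float, float]:
        """(A, V, D) identifying the direction-independent profile."""
        return (self.peak_accel, self.peak_vel, self.displacement)


@dataclass(frozen=True)
class Waveform:
    """Sampled platform command: acceleration, velocity and position.

    ``vel`` and ``pos`` are the exact integrals of the continuous-time
    piecewise-constant acceleration profile evaluated at the sample times;
    position starts at 0 and ends at the signed total displacement.
    """

    time: np.ndarray  # s, uniform grid plus the exact end time
    accel: np.ndarray  # deg/s^2
    vel: np.ndarray  # deg/s
    pos: np.ndarray  # deg
    spec: PerturbationSpec | None = None

    def __post_init__(self) -> None:
        n = len(self.time)
        if not (len(self.accel) == len(self.vel) == len(self.pos) == n):
            raise ValueError("waveform series must share one length")

    @property
    def final_pos(self) -> float:
        return float(self.pos[-1])


def _profile_times(spec: PerturbationSpec, quantize_to_grid: bool) -> tuple[float, float]:
    d1, d2 = spec.accel_duration, spec.plateau_duration
    if quantize_to_grid:
        dt = 1.0 / spec.command_rate
        d1 = round(d1 / dt) * dt
        d2 = round(d2 / dt) * dt
    return d1, d2


def _eval_profile(
    t: np.ndarray, a: float, v: float, d1: float, d2: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form accel/vel/pos of the unsigned trapezoid at times ``t``.

    Times before motion start return zeros and times after motion end hold
    the final values, so the profile can be evaluated on any trial grid.
    """
    t1, t2, t3 = d1, d1 + d2, 2 * d1 + d2
    pre = t < 0.0
    accel = np.select(
        [pre, t < t1, t < t2, t <= t3], [0.0, a, 0.0, -a], default=0.0
    )
    vel = np.select(
        [pre, t < t1, t < t2, t <= t3],
        [0.0, a * t, v, a * (t3 - t)],
        default=0.0,
    )
    # piecewise-quadratic position; the segment constants make it C^1
    p1 = 0.5 * a * t**2
    p2 = 0.5 * a * d1**2 + v * (t - t1)
    p3 = 0.5 * a * d1**2 + v * d2 + v * (t - t2) - 0.5 * a * (t - t2) ** 2
    p_end = v * d1 + v * d2  # = D when durations are exact
    pos = np.select([pre, t < t1, t < t2, t <= t3], [0.0, p1, p2, p3], default=p_end)
    return accel, vel, pos


def design_waveform(spec: PerturbationSpec, quantize_to_grid: bool = False) -> Waveform:
    """Construct the platform command waveform for one condition.

    The continuous-time acceleration profile (+A, 0, -A with exact block
    durations) is integrated analytically and sampled at ``command_rate``;
    the exact motion end time is appended when it falls off the grid so the
    final sample carries the full displacement.  Signs are flipped for
    negative directions (backward / rightward).
    """
    a, v = spec.peak_accel, spec.peak_vel
    d1, d2 = _profile_times(spec, quantize_to_grid)
    total = 2 * d1 + d2
    dt = 1.0 / spec.command_rate
    n_grid = int(np.floor(total / dt + 1e-9)) + 1
    t = np.arange(n_grid) * dt
    if total - t[-1] > 1e-12:
        t = np.append(t, total)
    # with quantized durations the plateau velocity v is still A*d1 only if
    # d1 was exact; recompute the plateau level so vel stays continuous
    v_eff = a * d1
    accel, vel, pos = _eval_profile(t, a, v_eff, d1, d2)
    s = float(spec.sign)
    return Waveform(time=t, accel=s * accel, vel=s * vel, pos=s * pos, spec=spec)


@dataclass(frozen=True)
class ProtocolConfig:
    """The condition grid of a velocity-set / acceleration-set protocol.

    The default values are the study grid: a base profile (40 deg/s at
    500 deg/s^2) shared between a velocity set {20, 40, 60} deg/s at fixed
    500 deg/s^2 and an acceleration set {200, 500, 1000} deg/s^2 at fixed
    40 deg/s, all with 10 deg total displacement, delivered in four
    directions (forward/backward pitch, leftward/rightward roll).
    """

    velocities: tuple[float, ...] = (20.0, 40.0, 60.0)
    accelerations: tuple[float, ...] = (200.0, 500.0, 1000.0)
    base_velocity: float = 40.0
    base_acceleration: float = 500.0
    displacement: float = 10.0
    axes: tuple[Axis, ...] = ("pitch", "roll")
    command_rate: float = 100.0

    def profiles(self) -> list[tuple[float, float]]:
        """De-duplicated (peak_accel, peak_vel) profiles, base first."""
        seen: dict[tuple[float, float], None] = {}
        seen[(self.base_acceleration, self.base_velocity)] = None
        for v in self.velocities:
            seen[(self.base_acceleration, v)] = None
        for a in self.accelerations:
            seen[(a, self.base_velocity)] = None
        return list(seen)


STUDY_PROTOCOL = ProtocolConfig()


def enumerate_conditions(protocol: ProtocolConfig = STUDY_PROTOCOL) -> list[PerturbationSpec]:
    """Enumerate the distinct perturbation conditions of a protocol.

    Returns the cross of the de-duplicated (A, V) profiles with the four
    tilt directions; the shared base profile appears once per direction.
    The study protocol yields 5 profiles x 4 directions = 20 conditions.
    """
    specs: list[PerturbationSpec] = []
    for (a, v), axis in itertools.product(protocol.profiles(), protocol.axes):
        for direction in _AXIS_DIRECTIONS[axis]:
            specs.append(
                PerturbationSpec(
                    axis=axis,
                    direction=direction,
                    peak_accel=a,
                    peak_vel=v,
                    displacement=protocol.displacement,
                    command_rate=protocol.command_rate,
                )
            )
    return specs


@dataclass(frozen=True)
class ValidationReport:
    """Self-consistency checks of a sampled waveform against its spec."""

    max_vel_error: float  # | max |vel| - V |, deg/s
    displacement_error: float  # | |final pos| - D |, deg
    max_accel_excess: float  # max |accel| - A (<= 0 when within bound), deg/s^2
    vel_ok: bool
    displacement_ok: bool
    accel_ok: bool

    @property
    def ok(self) -> bool:
        return self.vel_ok and self.displacement_ok and self.accel_ok


def validate_waveform(
    w: Waveform,
    spec: PerturbationSpec,
    vel_tol: float = 1e-9,
    disp_tol: float = 1e-9,
    accel_tol: float = 1e-9,
) -> ValidationReport:
    """Check a waveform's peak velocity, displacement and acceleration bound.

    The peak-velocity check compares max |vel| against V; because durations
    are handled in continuous time the plateau is sampled whenever it spans
    at least one command period (always true for the study conditions).
    """
    if not (len(w.time) == len(w.accel) == len(w.vel) == len(w.pos)):
        raise ValueError("waveform series must share one length")
    if len(w.time) == 0:
        raise ValueError("empty waveform")
    vel_err = abs(float(np.max(np.abs(w.vel))) - spec.peak_vel)
    disp_err = abs(abs(w.final_pos) - spec.displacement)
    accel_excess = float(np.max(np.abs(w.accel))) - spec.peak_accel
    return ValidationReport(
        max_vel_error=vel_err,
        displacement_error=disp_err,
        max_accel_excess=accel_excess,
        vel_ok=vel_err <= vel_tol,
        displacement_ok=disp_err <= disp_tol,
        accel_ok=accel_excess <= accel_tol,
    )


def mirror_spec(spec: PerturbationSpec) -> PerturbationSpec:
    """The same profile delivered in the opposite direction."""
    d1, d2 = _AXIS_DIRECTIONS[spec.axis]
    other = d2 if spec.direction == d1 else d1
    return replace(spec, direction=other)
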