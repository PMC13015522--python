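"""Dual-pendulum model of head and trunk motion during platform tilt.

The body is reduced to two rigid segments: a trunk-limb segment pivoting
about the ankles and a head segment articulated at the neck.  The platform
drives the trunk through a linear rotational spring-damper; the head is
coupled to the trunk through a second spring-damper.  With theta1 and
theta2 the trunk and head angles from vertical (rad) and phi the platform
angle, the segment torques are

    tau1 = -m1*g*l1*theta1 - k_platform*(theta1 - phi) - c_platform*(theta1' - phi')
    tau2 = -k_neck*(theta2 - theta1) - c_neck*(theta2' - theta1')

and the angular accelerations are theta1'' = tau1/I1, theta2'' = tau2/I2.
The model is linear and one-way coupled (the neck torque does not react on
the trunk); it carries no gravitational or inertial term on the head
segment.  The gravity term on the trunk is restoring as written; a
``gravity_sign`` switch flips it to the destabilizing inverted-pendulum
convention for sensitivity analyses.

The model is a conceptual tool: parameter profiles are representative, not
fitted.  Two named profiles reproduce the qualitatively distinct regimes of
platform-following (stiff platform coupling, compliant neck) and head
stabilization in space (compliant platform coupling, stiff neck).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from .design import PerturbationSpec, _eval_profile

__all__ = [
    "PendulumParams",
    "PendulumState",
    "PlatformDrive",
    "Trajectory",
    "compute_torques",
    "simulate",
    "static_equilibrium",
    "PARAM_PROFILES",
]

DEG2RAD = np.pi / 180.0

# Integrator settings: adaptive embedded Runge-Kutta with dense output,
# sampled on the 1000 samples/s analysis grid.
RTOL = 1e-8
ATOL = 1e-10
ANALYSIS_RATE = 1000.0


@dataclass(frozen=True)
class PendulumParams:
    """Segment and coupling constants.

    m1, l1, I1 : trunk mass (kg), COM distance (m), moment of inertia (kg m^2)
    I2 : head moment of inertia (kg m^2)
    k_platform, c_platform : trunk-platform stiffness (N m/rad) and damping (N m s/rad)
    k_neck, c_neck : head-trunk stiffness and damping, same units
    g : gravitational acceleration (m/s^2)
    gravity_sign : +1 keeps the restoring trunk gravity term as written;
        -1 gives the destabilizing inverted-pendulum convention.
    """

    m1: float
    l1: float
    I1: float
    I2: float
    k_platform: float
    c_platform: float
    k_neck: float
    c_neck: float
    g: float = 9.81
    gravity_sign: float = 1.0

    def __post_init__(self) -> None:
        for name in ("m1", "l1", "I1", "I2", "g"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("k_platform", "c_platform", "k_neck", "c_neck"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# Representative rhesus-scale values (illustrative, not fitted to data):
# ~7 kg trunk with COM ~0.18 m above the ankles.  The two regime profiles
# differ only in the coupling stiffnesses.
_BASE = dict(m1=7.0, l1=0.18, I1=0.35, I2=0.025, g=9.81)

PARAM_PROFILES: dict[str, PendulumParams] = {
    # balanced default
    "default": PendulumParams(**_BASE, k_platform=60.0, c_platform=4.0, k_neck=3.0, c_neck=0.3),
    # trunk rides the platform, neck compliant: platform-following regime
    "platform-following": PendulumParams(
        **_BASE, k_platform=2000.0, c_platform=80.0, k_neck=1.5, c_neck=0.25
    ),
    # weak platform coupling, stiff damped neck: head stabilized in space
    "stabilizing": PendulumParams(
        **_BASE, k_platform=8.0, c_platform=1.5, k_neck=40.0, c_neck=1.2
    ),
}


@dataclass(frozen=True)
class PendulumState:
    """Trunk/head angles from vertical (rad) and angular velocities (rad/s)."""

    theta1: float = 0.0
    theta2: float = 0.0
    omega1: float = 0.0
    omega2: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.theta1, self.theta2, self.omega1, self.omega2)
        if not np.all(np.isfinite(vals)):
            raise ValueError("state must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.theta1, self.theta2, self.omega1, self.omega2])


@dataclass(frozen=True)
class PlatformDrive:
    """Platform angle phi(t) and angular velocity phidot(t), rad / rad/s."""

    phi: Callable[[np.ndarray], np.ndarray]
    phidot: Callable[[np.ndarray], np.ndarray]

    @classmethod
    def from_spec(cls, spec: PerturbationSpec) -> "PlatformDrive":
        """Drive functions from a perturbation spec.

        Uses the same closed-form trapezoid integration as the waveform
        designer (converted deg -> rad), so the platform drive seen by the
        model is exactly consistent with the designed command.
        """
        a = spec.peak_accel * DEG2RAD
        d1, d2 = spec.accel_duration, spec.plateau_duration
        v = a * d1
        s = float(spec.sign)

        def phi(t: np.ndarray) -> np.ndarray:
            t = np.asarray(t, dtype=float)
            _, _, pos = _eval_profile(np.atleast_1d(t), a, v, d1, d2)
            return s * pos.reshape(np.shape(t))

        def phidot(t: np.ndarray) -> np.ndarray:
            t = np.asarray(t, dtype=float)
            _, vel, _ = _eval_profile(np.atleast_1d(t), a, v, d1, d2)
            return s * vel.reshape(np.shape(t))

        return cls(phi=phi, phidot=phidot)

    @classmethod
    def constant(cls, phi0: float) -> "PlatformDrive":
        """A platform held at a fixed angle (step drive)."""
        return cls(
            phi=lambda t: np.full(np.shape(t), phi0, dtype=float),
            phidot=lambda t: np.zeros(np.shape(t)),
        )

    @classmethod
    def zero(cls) -> "PlatformDrive":
        return cls.constant(0.0)


@dataclass(frozen=True)
class Trajectory:
    """Simulated head/trunk motion sampled on a uniform grid."""

    time: np.ndarray  # s
    theta1: np.ndarray  # rad
    theta2: np.ndarray
    omega1: np.ndarray  # rad/s
    omega2: np.ndarray
    tau1: np.ndarray  # N m
    tau2: np.ndarray

    def state_at(self, i: int) -> PendulumState:
        return PendulumState(
            float(self.theta1[i]), float(self.theta2[i]),
            float(self.omega1[i]), float(self.omega2[i]),
        )


def compute_torques(
    state: PendulumState, phi: float, phidot: float, params: PendulumParams
) -> tuple[float, float]:
    """Trunk and head torques (N m) for one state and platform sample."""
    p = params
    tau1 = (
        -p.gravity_sign * p.m1 * p.g * p.l1 * state.theta1
        - p.k_platform * (state.theta1 - phi)
        - p.c_platform * (state.omega1 - phidot)
    )
    tau2 = -p.k_neck * (state.theta2 - state.theta1) - p.c_neck * (state.omega2 - state.omega1)
    return float(tau1), float(tau2)


def _rhs(params: PendulumParams, drive: PlatformDrive) -> Callable[[float, np.ndarray], np.ndarray]:
    p = params

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        th1, th2, om1, om2 = y
        phi = float(drive.phi(t))
        phidot = float(drive.phidot(t))
        tau1 = (
            -p.gravity_sign * p.m1 * p.g * p.l1 * th1
            - p.k_platform * (th1 - phi)
            - p.c_platform * (om1 - phidot)
        )
        tau2 = -p.k_neck * (th2 - th1) - p.c_neck * (om2 - om1)
        return np.array([om1, om2, tau1 / p.I1, tau2 / p.I2])

    return rhs


def simulate(
    params: PendulumParams,
    drive: PlatformDrive,
    init: PendulumState | None = None,
    duration: float = 1.0,
    output_rate: float = ANALYSIS_RATE,
) -> Trajectory:
    """Integrate the model over [0, duration] and sample at ``output_rate``.

    Uses an adaptive RK45 integrator (rtol 1e-8, atol 1e-10) with dense
    output evaluated on the uniform output grid; deterministic given inputs.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    init = init or PendulumState()
    t_out = np.arange(int(round(duration * output_rate)) + 1) / output_rate
    sol = solve_ivp(
        _rhs(params, drive),
        (0.0, duration),
        init.as_array(),
        method="RK45",
        t_eval=t_out,
        rtol=RTOL,
        atol=ATOL,
        max_step=0.02,  # the drive is piecewise smooth; cap steps across block edges
    )
    if not sol.success:
        raise RuntimeError(f"integration failed near t = {sol.t[-1]:.4f} s: {sol.message}")
    th1, th2, om1, om2 = sol.y
    phi = np.asarray(drive.phi(sol.t), dtype=float)
    phidot = np.asarray(drive.phidot(sol.t), dtype=float)
    p = params
    tau1 = (
        -p.gravity_sign * p.m1 * p.g * p.l1 * th1
        - p.k_platform * (th1 - phi)
        - p.c_platform * (om1 - phidot)
    )
    tau2 = -p.k_neck * (th2 - th1) - p.c_neck * (om2 - om1)
    return Trajectory(time=sol.t, theta1=th1, theta2=th2, omega1=om1, omega2=om2,
                      tau1=tau1, tau2=tau2)


def static_equilibrium(params: PendulumParams, phi0: float) -> PendulumState:
    """Closed-form rest state under a constant platform angle.

    Solving tau1 = tau2 = 0 with zero rates gives

        theta1* = k_platform * phi0 / (gravity_sign * m1*g*l1 + k_platform)
        theta2* = theta1*

    which the simulated trajectory approaches for a step drive with
    nonzero damping (when the denominator is positive, i.e. the restoring
    regime).
    """
    denom = params.gravity_sign * params.m1 * params.g * params.l1 + params.k_platform
    if denom <= 0:
        raise ValueError("degenerate equilibrium: gravity_sign*m1*g*l1 + k_platform must be > 0")
    th = params.k_platform * phi0 / denom
    return PendulumState(theta1=th, theta2=th, omega1=0.0, omega2=0.0)
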