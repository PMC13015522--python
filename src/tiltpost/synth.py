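"""Synthetic perturbation-trial generator.

Because the study's animal recordings are not deposited, this module
synthesizes trial sets with the same structure — head kinematics, four
footplate forces, per-animal offsets, direction asymmetry and a known
fraction of QC-violating trials — so every pipeline stage can be exercised
against injectable ground truth.  The generator encodes the headline
finding as its data-generating process: the short-latency response
(first 100 ms) scales with stimulus angular acceleration and the
medium-latency response (100-200 ms) scales with peak stimulus velocity.

Per trial the perturbation-axis channels are built as delayed, noisy
mixtures of two raised-cosine response components:

- a short-latency component supported on [onset, 100) ms with amplitude
  ``short_accel_gain * peak_accel * animal offset``;
- a medium-latency component supported on [100, 200) ms with amplitude
  ``medium_vel_gain * peak_vel * animal offset``;

each normalized so its sampled mean over the corresponding analysis
window equals 1, making the generator/metric round trip exact at zero
noise.  Head channels are superposed on a passive base: pitch trials ride
the platform (head velocity equals the platform command), roll trials use
the dual-pendulum model's stabilizing profile (constrained head motion).
Force traces are synthesized by inverting the CoP equations, so the
kinetics stage recovers the target CoP exactly.

Randomness: one master seed; each trial draws from a counter-derived
substream, so any subset of trials is reproducible independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import PerturbationSpec, _eval_profile, enumerate_conditions
from .kinetics import CoPTrace, ForcePlateTrace
from .pendulum import PARAM_PROFILES, PlatformDrive, simulate
from .qc import TrialRecord

__all__ = [
    "GeneratorSpec",
    "generate_trial_set",
    "generate_force_traces",
    "ground_truth_table",
]

RAD2DEG = 180.0 / np.pi

# Study-condition defaults.  Channel gains are expressed for the CoP
# channel (N/kg); head channels scale the same response shape by fixed
# per-channel factors chosen to give realistic magnitudes (a few deg/s of
# head velocity, tenths of m/s^2 of linear acceleration).
DEFAULT_ANIMALS: dict[str, float] = {"monkey-1": 0.9, "monkey-2": 1.0, "monkey-3": 1.1}
DEFAULT_CHANNEL_SCALES: dict[str, float] = {"cop": 1.0, "angvel": 3.0, "linacc": 0.25}
DEFAULT_ONSET_MS: dict[str, float] = {"cop": 40.0, "angvel": 25.0, "linacc": 25.0}
DEFAULT_NOISE_SD: dict[str, float] = {"cop": 0.15, "angvel": 1.0, "linacc": 0.05}


@dataclass(frozen=True)
class GeneratorSpec:
    """Ground-truth parameters of a synthetic trial set.

    ``n_trials`` is per condition and animal (the study collected >= 20
    trials per condition per animal).  ``short_accel_gain`` (N/kg per
    deg/s^2) and ``medium_vel_gain`` (N/kg per deg/s) set the CoP-channel
    response amplitudes; per-animal multiplicative offsets average 1 so
    pooled regressions recover the gains unbiasedly.
    ``direction_asymmetry`` multiplies response amplitudes of the
    negative direction of each axis (1.0 = mirror-symmetric).
    ``contamination_rate`` is the fraction of trials given QC-violating
    artifacts (pre-onset drift, a > 400 deg/s head-shake spike, or a
    stepping flag), emulating the study's ~10% exclusion rate.
    """

    conditions: tuple[PerturbationSpec, ...] = field(
        default_factory=lambda: tuple(enumerate_conditions())
    )
    n_trials: int = 20
    animals: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ANIMALS))
    short_accel_gain: float = 2.0e-3  # N/kg per deg/s^2
    medium_vel_gain: float = 2.0e-2  # N/kg per deg/s
    channel_scales: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_SCALES)
    )
    onset_ms: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ONSET_MS))
    noise_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    direction_asymmetry: float = 1.0
    contamination_rate: float = 0.1
    include_base: bool = True
    mass_kg: float = 7.0
    baseline_load_n: float | None = None  # default mass*g/4 per plate
    analysis_rate: float = 1000.0
    pre_span_s: float = 0.5
    post_span_s: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 0.0 <= self.contamination_rate <= 1.0:
            raise ValueError("contamination_rate must be in [0, 1]")
        for name, d in (("noise_sd", self.noise_sd),):
            if any(v < 0 for v in d.values()):
                raise ValueError(f"{name} entries must be >= 0")
        if not self.conditions:
            raise ValueError("at least one condition is required")
        if not np.all(np.isfinite([self.short_accel_gain, self.medium_vel_gain])):
            raise ValueError("gains must be finite")


def generate_force_traces(
    cop_target: CoPTrace, mass: float, baseline_load: float
) -> ForcePlateTrace:
    """Four footplate force series whose CoP equals ``cop_target``.

    Inverts the CoP equations with the canonical equal split: the force
    difference required by each CoP component is distributed equally
    across the two plates of the corresponding half, on top of an equal
    baseline load per plate.  Raises when any plate would need a negative
    (tensile) force.
    """
    if baseline_load <= 0:
        raise ValueError("baseline_load must be > 0")
    if mass <= 0:
        raise ValueError("mass must be > 0")
    dl = mass * np.asarray(cop_target.lat, dtype=float) / 4.0
    da = mass * np.asarray(cop_target.ap, dtype=float) / 4.0
    ffl = baseline_load + dl + da
    ffr = baseline_load - dl + da
    fhl = baseline_load + dl - da
    fhr = baseline_load - dl - da
    lo = min(float(np.min(f)) for f in (ffl, ffr, fhl, fhr))
    if lo < 0:
        raise ValueError(
            f"infeasible CoP target: a plate force would reach {lo:.3f} N; "
            "increase baseline_load"
        )
    return ForcePlateTrace(
        time=np.asarray(cop_target.time, dtype=float),
        F_FL=ffl, F_FR=ffr, F_HL=fhl, F_HR=fhr, mass=mass,
    )


def _raised_cosine(t: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """Raised-cosine bump supported on [t0, t1), zero elsewhere."""
    out = np.zeros_like(t)
    mask = (t >= t0) & (t < t1)
    out[mask] = 0.5 * (1.0 - np.cos(2.0 * np.pi * (t[mask] - t0) / (t1 - t0)))
    return out


def _window_normalized_bump(
    t: np.ndarray, support: tuple[float, float], window: tuple[float, float]
) -> np.ndarray:
    """Bump on ``support`` scaled to unit sampled mean over ``window``."""
    bump = _raised_cosine(t, *support)
    in_window = (t >= window[0]) & (t < window[1])
    m = float(np.mean(bump[in_window]))
    if m <= 0:
        raise ValueError("response support does not overlap the analysis window")
    return bump / m


def _trial_grid(spec: GeneratorSpec, cond: PerturbationSpec) -> np.ndarray:
    rate = spec.analysis_rate
    n_pre = int(round(spec.pre_span_s * rate))
    n_post = int(round((cond.motion_duration + spec.post_span_s) * rate))
    return np.arange(-n_pre, n_post + 1) / rate


# The passive base is a pure function of the condition and grid; cache it
# across generator invocations (repeated-generation studies re-use it).
_BASE_CACHE: dict[tuple, np.ndarray] = {}


def _base_head_angvel(spec: GeneratorSpec, cond: PerturbationSpec, t: np.ndarray) -> np.ndarray:
    """Passive head angular velocity base, deg/s, on the trial grid.

    Pitch: platform-following (head velocity = platform command).
    Roll: dual-pendulum stabilizing profile (constrained head motion).
    """
    key = (cond.axis, cond.direction, cond.profile_key, spec.analysis_rate, len(t), float(t[0]))
    cached = _BASE_CACHE.get(key)
    if cached is not None:
        return cached
    out = _base_head_angvel_uncached(spec, cond, t)
    _BASE_CACHE[key] = out
    return out


def _base_head_angvel_uncached(
    spec: GeneratorSpec, cond: PerturbationSpec, t: np.ndarray
) -> np.ndarray:
    if cond.axis == "pitch":
        a = cond.peak_accel
        d1, d2 = cond.accel_duration, cond.plateau_duration
        _, vel, _ = _eval_profile(t, a, a * d1, d1, d2)
        return cond.sign * vel
    drive = PlatformDrive.from_spec(cond)
    traj = simulate(
        PARAM_PROFILES["stabilizing"],
        drive,
        duration=float(t[-1]),
        output_rate=spec.analysis_rate,
    )
    out = np.zeros_like(t)
    post = t >= 0.0
    # trajectory grid starts at 0 and matches the trial's post-onset samples
    out[post] = traj.omega2[: int(np.sum(post))] * RAD2DEG
    return out


def _contaminate(
    t: np.ndarray, angvel: np.ndarray, kind: str, motion_end: float
) -> tuple[np.ndarray, bool]:
    """Inject one QC-violating artifact; returns (angvel, step_flag)."""
    angvel = angvel.copy()
    if kind == "baseline-drift":
        # slow pre-onset head movement peaking at 30 deg/s (> 20 deg/s rule)
        pre = t < 0.0
        angvel[pre, 0] += 30.0 * np.sin(2.0 * np.pi * (t[pre] - t[0]))
    elif kind == "head-shake":
        # 450 deg/s spike in the post-offset tail (> 400 deg/s rule)
        spike = 450.0 * _raised_cosine(t, motion_end + 0.1, motion_end + 0.2)
        angvel[:, 2] += spike
    elif kind == "step":
        return angvel, True
    else:
        raise ValueError(f"unknown artifact {kind!r}")
    return angvel, False


_ARTIFACTS = ("baseline-drift", "head-shake", "step")


def generate_trial_set(spec: GeneratorSpec) -> list[TrialRecord]:
    """Generate the full synthetic trial set for a generator spec.

    Iterates conditions x animals x trials; each trial uses an
    independent counter-derived RNG substream of the master seed and
    records its ground truth (response amplitudes, contamination) in
    ``TrialRecord.meta``.
    """
    baseline_load = (
        spec.baseline_load_n
        if spec.baseline_load_n is not None
        else spec.mass_kg * 9.81 / 4.0
    )
    base_cache: dict[tuple, np.ndarray] = {}
    trials: list[TrialRecord] = []
    counter = 0
    for cond in spec.conditions:
        t = _trial_grid(spec, cond)
        ckey = (cond.axis, cond.direction, cond.profile_key)
        if ckey not in base_cache:
            base_cache[ckey] = _base_head_angvel(spec, cond, t)
        base = base_cache[ckey]
        short_bump = _window_normalized_bump(
            t, (spec.onset_ms["cop"] / 1000.0, 0.100), (0.0, 0.100)
        )
        medium_bump = _window_normalized_bump(t, (0.100, 0.200), (0.100, 0.200))
        head_short = _window_normalized_bump(
            t, (spec.onset_ms["angvel"] / 1000.0, 0.100), (0.0, 0.100)
        )
        dir_gain = 1.0 if cond.sign > 0 else spec.direction_asymmetry
        for animal_id, offset in spec.animals.items():
            for k in range(spec.n_trials):
                rng = np.random.default_rng([spec.seed, counter])
                amp_s = spec.short_accel_gain * cond.peak_accel * offset * dir_gain
                amp_m = spec.medium_vel_gain * cond.peak_vel * offset * dir_gain
                sgn = float(cond.sign)
                n = len(t)

                angvel = rng.normal(0.0, spec.noise_sd["angvel"], size=(n, 3))
                ai = 0 if cond.axis == "pitch" else 1
                scale_w = spec.channel_scales["angvel"]
                angvel[:, ai] += sgn * scale_w * (amp_s * head_short + amp_m * medium_bump)
                if spec.include_base:
                    angvel[:, ai] += base

                linacc = rng.normal(0.0, spec.noise_sd["linacc"], size=(n, 3))
                li = 0 if cond.axis == "pitch" else 1
                scale_a = spec.channel_scales["linacc"]
                linacc[:, li] += sgn * scale_a * (amp_s * head_short + amp_m * medium_bump)

                cop_resp = sgn * (amp_s * short_bump + amp_m * medium_bump)
                cop_resp = cop_resp + rng.normal(0.0, spec.noise_sd["cop"], size=n)
                cop_other = rng.normal(0.0, spec.noise_sd["cop"], size=n)
                if cond.axis == "roll":
                    cop = CoPTrace(time=t, lat=cop_resp, ap=cop_other)
                else:
                    cop = CoPTrace(time=t, lat=cop_other, ap=cop_resp)
                forces = generate_force_traces(cop, spec.mass_kg, baseline_load)

                contaminated = bool(rng.random() < spec.contamination_rate)
                artifact = None
                step_flag = False
                if contaminated:
                    artifact = _ARTIFACTS[int(rng.integers(len(_ARTIFACTS)))]
                    angvel, step_flag = _contaminate(t, angvel, artifact, cond.motion_duration)

                trials.append(
                    TrialRecord(
                        trial_id=f"t{counter:05d}",
                        animal_id=animal_id,
                        condition=cond,
                        time=t,
                        head_angvel=angvel,
                        head_linacc=linacc,
                        forces=forces,
                        step_response_flag=step_flag,
                        meta={
                            "contaminated": contaminated,
                            "artifact": artifact,
                            "animal_offset": offset,
                            "amp_short_cop": sgn * amp_s,
                            "amp_medium_cop": sgn * amp_m,
                            "trial_index": k,
                        },
                    )
                )
                counter += 1
    return trials


def ground_truth_table(trials: list[TrialRecord]) -> pd.DataFrame:
    """Tidy per-trial ground-truth bookkeeping for test harnesses."""
    rows = []
    for tr in trials:
        rows.append(
            {
                "trial_id": tr.trial_id,
                "animal_id": tr.animal_id,
                "axis": tr.condition.axis,
                "direction": tr.condition.direction,
                "peak_accel_dps2": tr.condition.peak_accel,
                "peak_vel_dps": tr.condition.peak_vel,
                "contaminated": tr.meta.get("contaminated", False),
                "artifact": tr.meta.get("artifact"),
                "amp_short_cop": tr.meta.get("amp_short_cop"),
                "amp_medium_cop": tr.meta.get("amp_medium_cop"),
            }
        )
    return pd.DataFrame(rows)
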