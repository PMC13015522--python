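"""Response metrics for perturbation trials.

The postural response is quantified in two temporal phases: a
short-latency window covering the first 100 ms after perturbation onset
and a medium-latency window covering 100-200 ms.  Windows are half-open
([0, 100) and [100, 200) ms) so the boundary sample is not counted twice.
Per trial and channel this module computes:

- window means over the two phases;
- response-onset latency: the first post-onset time at which the signal
  deviates from its baseline mean by more than the RMS of the 500 ms
  pre-onset baseline (mean-subtracted), with an epsilon floor for
  noiseless baselines and an optional consecutive-sample requirement;
- total angular displacement (integral of angular velocity), total linear
  displacement (double integral of linear acceleration) and CoP trajectory
  length (cumulated absolute CoP increment), all over the platform-motion
  span;
- per-condition averages (pointwise mean and SEM across trials) and
  mirror-direction pooling (inverting one direction's direction-odd
  channels and concatenating the trial sets).

Integration uses the trapezoidal rule on the analysis grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid, trapezoid

from .design import mirror_spec
from .kinetics import CoPTrace, ForcePlateTrace, compute_cop
from .qc import TrialRecord

__all__ = [
    "SHORT_WINDOW",
    "MEDIUM_WINDOW",
    "ResponseMetrics",
    "ConditionAverage",
    "window_mean",
    "onset_latency",
    "displacements",
    "average_condition",
    "invert_and_pool",
    "trial_metrics",
    "metrics_table",
]

SHORT_WINDOW = (0.0, 0.100)  # s, [0, 100) ms after onset
MEDIUM_WINDOW = (0.100, 0.200)  # s, [100, 200) ms
BASELINE_SPAN = 0.5  # s of pre-onset baseline
EPS_FLOOR = 1e-9  # onset threshold floor, channel units


def window_mean(time: np.ndarray, values: np.ndarray, window: tuple[float, float]) -> float:
    """Arithmetic mean of the samples with window[0] <= t < window[1]."""
    t0, t1 = window
    mask = (time >= t0) & (time < t1)
    if not np.any(mask):
        raise ValueError(f"window [{t0}, {t1}) s contains no samples")
    return float(np.mean(values[mask]))


def onset_latency(
    time: np.ndarray,
    values: np.ndarray,
    baseline_span: float = BASELINE_SPAN,
    eps_floor: float = EPS_FLOOR,
    n_consecutive: int = 1,
) -> float | None:
    """Response-onset latency in ms, or None when no onset is detected.

    The detection threshold is the RMS of the mean-subtracted baseline
    (the ``baseline_span`` seconds preceding t = 0), floored at
    ``eps_floor``.  Latency is the first post-onset time at which
    |signal - baseline mean| exceeds the threshold for ``n_consecutive``
    successive samples.
    """
    baseline = (time >= -baseline_span) & (time < 0.0)
    if not np.any(baseline):
        raise ValueError("no baseline samples before onset")
    base = values[baseline]
    base_mean = float(np.mean(base))
    threshold = max(float(np.sqrt(np.mean((base - base_mean) ** 2))), eps_floor)
    post = time >= 0.0
    dev = np.abs(values[post] - base_mean)
    above = dev > threshold
    if n_consecutive > 1:
        kernel = np.ones(n_consecutive, dtype=int)
        runs = np.convolve(above.astype(int), kernel, mode="valid") == n_consecutive
        idx = np.flatnonzero(runs)
    else:
        idx = np.flatnonzero(above)
    if idx.size == 0:
        return None
    return float(time[post][idx[0]] * 1000.0)


def displacements(
    trial: TrialRecord,
    span: tuple[float, float] | None = None,
    cop: CoPTrace | None = None,
) -> tuple[float, float, float]:
    """Total displacements over the platform-motion span.

    Returns ``(angular_deg, linear_m, cop_path)`` for the trial's
    perturbation-axis channels: the trapezoidal integral of head angular
    velocity, the double trapezoidal integral of head linear acceleration,
    and the CoP path length (sum of absolute sample-to-sample CoP
    increments, N/kg).  ``span`` defaults to [0, motion end] — the
    waveform's analytic motion duration.
    """
    t0, t1 = span if span is not None else (0.0, trial.motion_end)
    # half-sample tolerance so a span edge that rounds a hair past a grid
    # point still includes that sample
    eps = 0.5 / trial.rate
    if t0 < trial.time[0] - eps or t1 > trial.time[-1] + eps:
        raise ValueError(
            f"span [{t0:.3f}, {t1:.3f}] s outside trial span "
            f"[{trial.time[0]:.3f}, {trial.time[-1]:.3f}] s"
        )
    mask = (trial.time >= t0 - eps) & (trial.time <= t1 + eps)
    t = trial.time[mask]
    angvel = trial.angvel_channel()[mask]
    linacc = trial.linacc_channel()[mask]
    angular = float(trapezoid(angvel, t))
    linvel = cumulative_trapezoid(linacc, t, initial=0.0)
    linear = float(trapezoid(linvel, t))
    cop = cop if cop is not None else compute_cop(trial.forces)
    cop_axis = cop.channel(trial.condition.axis)[mask]
    cop_path = float(np.sum(np.abs(np.diff(cop_axis))))
    return angular, linear, cop_path


@dataclass(frozen=True)
class ResponseMetrics:
    """Window means, onset latencies and displacements for one trial.

    Per-channel entries are keyed ``angvel``, ``linacc`` and ``cop`` — the
    head angular velocity, head linear acceleration and CoP components
    along the trial's perturbation axis.
    """

    trial_id: str
    animal_id: str
    short_mean: dict[str, float]
    medium_mean: dict[str, float]
    onset_latency_ms: dict[str, float | None]
    total_angular_displacement: float  # deg
    total_linear_displacement: float  # m
    cop_path_length: float  # N/kg


def trial_metrics(trial: TrialRecord, n_consecutive: int = 1) -> ResponseMetrics:
    """Compute all response metrics of one trial on its axis channels."""
    cop = compute_cop(trial.forces)
    channels = {
        "angvel": trial.angvel_channel(),
        "linacc": trial.linacc_channel(),
        "cop": cop.channel(trial.condition.axis),
    }
    short = {k: window_mean(trial.time, v, SHORT_WINDOW) for k, v in channels.items()}
    medium = {k: window_mean(trial.time, v, MEDIUM_WINDOW) for k, v in channels.items()}
    onset = {
        k: onset_latency(trial.time, v, n_consecutive=n_consecutive)
        for k, v in channels.items()
    }
    angular, linear, cop_path = displacements(trial, cop=cop)
    return ResponseMetrics(
        trial_id=trial.trial_id,
        animal_id=trial.animal_id,
        short_mean=short,
        medium_mean=medium,
        onset_latency_ms=onset,
        total_angular_displacement=angular,
        total_linear_displacement=linear,
        cop_path_length=cop_path,
    )


def metrics_table(trials: list[TrialRecord], n_consecutive: int = 1) -> pd.DataFrame:
    """Tidy table: one row per trial and channel.

    Columns carry the trial identity, the condition parameters and the
    per-channel metric values; displacement is the channel-appropriate
    total (angular for ``angvel``, linear for ``linacc``, path length for
    ``cop``).
    """
    rows = []
    for trial in trials:
        m = trial_metrics(trial, n_consecutive=n_consecutive)
        spec = trial.condition
        disp = {
            "angvel": m.total_angular_displacement,
            "linacc": m.total_linear_displacement,
            "cop": m.cop_path_length,
        }
        for ch in ("angvel", "linacc", "cop"):
            rows.append(
                {
                    "trial_id": m.trial_id,
                    "animal_id": m.animal_id,
                    "axis": spec.axis,
                    "direction": spec.direction,
                    "peak_accel_dps2": spec.peak_accel,
                    "peak_vel_dps": spec.peak_vel,
                    "channel": ch,
                    "short_mean": m.short_mean[ch],
                    "medium_mean": m.medium_mean[ch],
                    "onset_latency_ms": m.onset_latency_ms[ch],
                    "displacement": disp[ch],
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ConditionAverage:
    """Pointwise mean and SEM traces across trials of one condition."""

    time: np.ndarray
    mean: dict[str, np.ndarray]
    sem: dict[str, np.ndarray]
    n_trials: int


_CHANNEL_KEYS = ("angvel", "linacc", "cop_lat", "cop_ap")


def _trial_channels(trial: TrialRecord) -> dict[str, np.ndarray]:
    cop = compute_cop(trial.forces)
    return {
        "angvel": trial.angvel_channel(),
        "linacc": trial.linacc_channel(),
        "cop_lat": cop.lat,
        "cop_ap": cop.ap,
    }


def average_condition(trials: list[TrialRecord]) -> ConditionAverage:
    """Synchronized across-trial mean and SEM per channel.

    All trials must share the same condition and time grid and be aligned
    at t = 0 (perturbation onset).  SEM is the sample standard deviation
    (ddof 1) divided by sqrt(n); it is 0 when n = 1.
    """
    if not trials:
        raise ValueError("no trials to average")
    key = (trials[0].condition.profile_key, trials[0].condition.axis, trials[0].condition.direction)
    for tr in trials[1:]:
        if (tr.condition.profile_key, tr.condition.axis, tr.condition.direction) != key:
            raise ValueError("trials mix perturbation conditions")
        if len(tr.time) != len(trials[0].time) or not np.allclose(tr.time, trials[0].time):
            raise ValueError("trials are not on a shared time grid")
    n = len(trials)
    stacked = {
        ch: np.stack([_trial_channels(tr)[ch] for tr in trials]) for ch in _CHANNEL_KEYS
    }
    mean = {ch: np.mean(arr, axis=0) for ch, arr in stacked.items()}
    if n == 1:
        sem = {ch: np.zeros_like(mean[ch]) for ch in _CHANNEL_KEYS}
    else:
        sem = {ch: np.std(arr, axis=0, ddof=1) / np.sqrt(n) for ch, arr in stacked.items()}
    return ConditionAverage(time=trials[0].time.copy(), mean=mean, sem=sem, n_trials=n)


def _mirror_trial(trial: TrialRecord) -> TrialRecord:
    """Invert a trial's direction-odd channels onto the mirror direction.

    For roll, the left/right plates are swapped (flipping CoP_lat) and the
    roll/yaw angular velocities and lateral acceleration are negated; for
    pitch, front/hind plates are swapped (flipping CoP_ap) and the pitch
    angular velocity and fore-aft acceleration are negated.
    """
    axis = trial.condition.axis
    angvel = trial.head_angvel.copy()
    linacc = trial.head_linacc.copy()
    f = trial.forces
    if axis == "roll":
        angvel[:, 1] *= -1.0  # roll
        angvel[:, 2] *= -1.0  # yaw
        linacc[:, 1] *= -1.0  # lateral
        forces = ForcePlateTrace(
            time=f.time, F_FL=f.F_FR, F_FR=f.F_FL, F_HL=f.F_HR, F_HR=f.F_HL, mass=f.mass
        )
    else:
        angvel[:, 0] *= -1.0  # pitch
        linacc[:, 0] *= -1.0  # fore-aft
        forces = ForcePlateTrace(
            time=f.time, F_FL=f.F_HL, F_FR=f.F_HR, F_HL=f.F_FL, F_HR=f.F_FR, mass=f.mass
        )
    return replace(
        trial,
        condition=mirror_spec(trial.condition),
        head_angvel=angvel,
        head_linacc=linacc,
        forces=forces,
    )


def invert_and_pool(
    reference_trials: list[TrialRecord], mirrored_trials: list[TrialRecord]
) -> list[TrialRecord]:
    """Pool mirror-direction trial sets after inverting one side.

    ``mirrored_trials`` must be the opposite direction of the same profile
    as ``reference_trials``; their direction-odd channels are sign-flipped
    and the sets concatenated (e.g. 20 + 20 -> 40 trials per condition).
    If one side is empty the other is returned unchanged with a warning.
    """
    if not reference_trials:
        warnings.warn("reference side empty; returning mirrored side unchanged")
        return list(mirrored_trials)
    if not mirrored_trials:
        warnings.warn("mirrored side empty; returning reference side unchanged")
        return list(reference_trials)
    ref = reference_trials[0].condition
    for tr in mirrored_trials:
        c = tr.condition
        if (
            c.axis != ref.axis
            or c.profile_key != ref.profile_key
            or c.direction == ref.direction
        ):
            raise ValueError(
                "mirrored trials must share the reference profile and axis "
                "with the opposite direction"
            )
    return list(reference_trials) + [_mirror_trial(tr) for tr in mirrored_trials]
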