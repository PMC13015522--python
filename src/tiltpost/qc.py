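"""Trial records and quality-control exclusion rules.

A trial is excluded when any of three rules fires:

- ``step-response``: video review flagged a stepping response (consumed
  here as an upstream boolean per trial);
- ``baseline-velocity``: head angular velocity in the 500 ms preceding
  perturbation onset exceeds 20 deg/s on any axis (the animal was moving
  before the trial);
- ``peak-velocity``: head angular velocity anywhere in the trial, from
  500 ms before onset through 500 ms after motion offset, exceeds
  400 deg/s on any axis (head shaking or other voluntary movement).

Thresholds are applied as strict "exceeds" on the per-axis absolute value;
a vector-norm mode is available by configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import PerturbationSpec
from .kinetics import ForcePlateTrace

__all__ = [
    "ANGVEL_AXES",
    "LINACC_AXES",
    "TrialRecord",
    "QCThresholds",
    "QCResult",
    "qc_trial",
    "summarize_exclusions",
]

# Channel order of the head kinematic arrays.
ANGVEL_AXES = ("pitch", "roll", "yaw")  # deg/s
LINACC_AXES = ("fore_aft", "lateral", "vertical")  # m/s^2

# Head channels aligned with each perturbation axis.
AXIS_ANGVEL_INDEX = {"pitch": 0, "roll": 1}
AXIS_LINACC_INDEX = {"pitch": 0, "roll": 1}


@dataclass(frozen=True)
class TrialRecord:
    """One trial: head kinematics, footplate forces, and metadata.

    Time is in seconds with t = 0 at perturbation onset; the grid is
    uniform at the analysis rate and must span at least 500 ms before
    onset and 500 ms past motion offset.  ``head_angvel`` (deg/s) and
    ``head_linacc`` (m/s^2) are (n_samples, 3) arrays in the channel order
    of ``ANGVEL_AXES`` / ``LINACC_AXES``.
    """

    trial_id: str
    animal_id: str
    condition: PerturbationSpec
    time: np.ndarray
    head_angvel: np.ndarray
    head_linacc: np.ndarray
    forces: ForcePlateTrace
    step_response_flag: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.time)
        if self.head_angvel.shape != (n, 3) or self.head_linacc.shape != (n, 3):
            raise ValueError("head kinematic arrays must be (n_samples, 3)")
        if len(self.forces.time) != n:
            raise ValueError("force trace length must match trial grid")
        if self.time[0] > -0.5 + 1e-9:
            raise ValueError(
                f"trial must span >= 500 ms before onset (starts at {self.time[0]:.3f} s)"
            )

    @property
    def motion_end(self) -> float:
        """Platform motion offset time, s (from the condition's waveform)."""
        return self.condition.motion_duration

    @property
    def rate(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.time)))

    def angvel_channel(self, axis: str | None = None) -> np.ndarray:
        axis = axis or self.condition.axis
        return self.head_angvel[:, AXIS_ANGVEL_INDEX[axis]]

    def linacc_channel(self, axis: str | None = None) -> np.ndarray:
        axis = axis or self.condition.axis
        return self.head_linacc[:, AXIS_LINACC_INDEX[axis]]


@dataclass(frozen=True)
class QCThresholds:
    """Exclusion thresholds; defaults are the study values."""

    baseline_vel_dps: float = 20.0
    peak_vel_dps: float = 400.0
    baseline_span_s: float = 0.5
    tail_span_s: float = 0.5
    use_vector_norm: bool = False


@dataclass(frozen=True)
class QCResult:
    """Keep/exclude decision for one trial; ``keep`` iff no rule fired."""

    trial_id: str
    animal_id: str
    keep: bool
    reasons: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.keep != (len(self.reasons) == 0):
            raise ValueError("keep must be True exactly when reasons is empty")


def _speed(angvel: np.ndarray, use_norm: bool) -> np.ndarray:
    if use_norm:
        return np.linalg.norm(angvel, axis=1)
    return np.max(np.abs(angvel), axis=1)


def qc_trial(trial: TrialRecord, thresholds: QCThresholds = QCThresholds()) -> QCResult:
    """Apply the exclusion rules to one trial."""
    th = thresholds
    t = trial.time
    if t[0] > -th.baseline_span_s + 1e-9:
        raise ValueError(
            f"insufficient pre-onset span: trial starts at {t[0]:.3f} s, "
            f"need {-th.baseline_span_s:.3f} s"
        )
    speed = _speed(trial.head_angvel, th.use_vector_norm)
    reasons: list[str] = []
    if trial.step_response_flag:
        reasons.append("step-response")
    baseline = (t >= -th.baseline_span_s) & (t < 0.0)
    if np.max(speed[baseline]) > th.baseline_vel_dps:
        reasons.append("baseline-velocity")
    window = (t >= -th.baseline_span_s) & (t <= trial.motion_end + th.tail_span_s)
    if np.max(speed[window]) > th.peak_vel_dps:
        reasons.append("peak-velocity")
    return QCResult(
        trial_id=trial.trial_id,
        animal_id=trial.animal_id,
        keep=not reasons,
        reasons=tuple(reasons),
    )


def summarize_exclusions(results: list[QCResult]) -> pd.DataFrame:
    """Per-animal exclusion counts and fractions, with per-reason counts.

    Returns one row per animal plus a pooled ``all`` row, with columns
    n_trials, n_excluded, fraction_excluded and one ``n_<reason>`` column
    per rule that fired anywhere.
    """
    if not results:
        raise ValueError("no QC results to summarize")
    rows = [
        {"animal_id": r.animal_id, "excluded": not r.keep, "reasons": r.reasons}
        for r in results
    ]
    df = pd.DataFrame(rows)
    all_reasons = sorted({reason for r in results for reason in r.reasons})

    def summarize(group: pd.DataFrame) -> dict:
        out = {
            "n_trials": len(group),
            "n_excluded": int(group["excluded"].sum()),
            "fraction_excluded": float(group["excluded"].mean()),
        }
        for reason in all_reasons:
            out[f"n_{reason}"] = int(
                sum(reason in rs for rs in group["reasons"])
            )
        return out

    records = {aid: summarize(g) for aid, g in df.groupby("animal_id")}
    records["all"] = summarize(df)
    out = pd.DataFrame.from_dict(records, orient="index")
    out.index.name = "animal_id"
    return out.reset_index()
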