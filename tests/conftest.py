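import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tiltpost.design import PerturbationSpec
from tiltpost.kinetics import ForcePlateTrace
from tiltpost.qc import TrialRecord

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

BASE = dict(peak_accel=500.0, peak_vel=40.0, displacement=10.0)


@pytest.fixture
def base_spec() -> PerturbationSpec:
    """The shared base perturbation: 500 deg/s^2, 40 deg/s, 10 deg."""
    return PerturbationSpec(axis="pitch", direction="forward", **BASE)


@pytest.fixture
def roll_spec() -> PerturbationSpec:
    return PerturbationSpec(axis="roll", direction="leftward", **BASE)


def make_trial(
    condition: PerturbationSpec,
    angvel: np.ndarray | None = None,
    linacc: np.ndarray | None = None,
    rate: float = 1000.0,
    pre: float = 0.5,
    post: float = 0.5,
    step_flag: bool = False,
    baseline_load: float = 20.0,
    trial_id: str = "t0",
    animal_id: str = "a0",
) -> TrialRecord:
    """A minimal trial on the analysis grid with constant symmetric forces."""
    n_pre = int(round(pre * rate))
    n_post = int(round((condition.motion_duration + post) * rate))
    t = np.arange(-n_pre, n_post + 1) / rate
    n = len(t)
    if angvel is None:
        angvel = np.zeros((n, 3))
    if linacc is None:
        linacc = np.zeros((n, 3))
    const = np.full(n, baseline_load)
    forces = ForcePlateTrace(
        time=t, F_FL=const, F_FR=const.copy(), F_HL=const.copy(), F_HR=const.copy(),
        mass=7.0,
    )
    return TrialRecord(
        trial_id=trial_id,
        animal_id=animal_id,
        condition=condition,
        time=t,
        head_angvel=angvel,
        head_linacc=linacc,
        forces=forces,
        step_response_flag=step_flag,
    )
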