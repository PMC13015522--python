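"""Window means, onset latency, displacements, averaging, mirror pooling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tiltpost.design import mirror_spec
from tiltpost.kinetics import compute_cop
from tiltpost.metrics import (
    MEDIUM_WINDOW,
    SHORT_WINDOW,
    average_condition,
    displacements,
    invert_and_pool,
    onset_latency,
    window_mean,
)

from conftest import make_trial


def grid(pre=0.5, post=0.8, rate=1000.0):
    n_pre = int(pre * rate)
    n_post = int(post * rate)
    return np.arange(-n_pre, n_post + 1) / rate


class TestWindowMean:
    def test_constant_trace(self):
        t = grid()
        assert window_mean(t, np.full_like(t, 3.7), SHORT_WINDOW) == pytest.approx(3.7)

    def test_ramp_mean_is_closed_form(self):
        """Ramp hitting 0..99 on the 100 short-window samples averages 49.5."""
        t = grid()
        values = np.where(t >= 0, t * 1000.0, 0.0)
        assert window_mean(t, values, SHORT_WINDOW) == pytest.approx(49.5)

    def test_windows_are_half_open(self):
        t = grid()
        values = np.where(t >= 0.1, 5.0, 0.0)
        assert window_mean(t, values, MEDIUM_WINDOW) == pytest.approx(5.0)
        assert window_mean(t, values, SHORT_WINDOW) == pytest.approx(0.0)

    @given(a=st.floats(-5, 5), b=st.floats(-5, 5))
    def test_linearity(self, a, b):
        t = grid()
        x = np.sin(10 * t)
        lhs = window_mean(t, a * x + b, SHORT_WINDOW)
        rhs = a * window_mean(t, x, SHORT_WINDOW) + b
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_empty_window_is_error(self):
        t = grid()
        with pytest.raises(ValueError, match="no samples"):
            window_mean(t, np.zeros_like(t), (2.0, 2.1))


class TestOnsetLatency:
    def test_noiseless_step_at_30ms(self):
        t = grid()
        values = np.where(t >= 0.030, 1.0, 0.0)
        assert onset_latency(t, values) == pytest.approx(30.0)

    def test_flat_trace_not_detected(self):
        t = grid()
        assert onset_latency(t, np.zeros_like(t)) is None

    def test_matches_brute_force_scan(self):
        """On seeded noisy ramps the fast path equals a literal sample scan."""
        rng = np.random.default_rng(11)
        t = grid()
        for _ in range(50):
            values = rng.normal(0, 1.0, t.shape)
            slope = rng.uniform(5.0, 50.0)
            values[t >= 0] += slope * t[t >= 0]
            got = onset_latency(t, values)
            base = values[(t >= -0.5) & (t < 0)]
            thr = max(np.sqrt(np.mean((base - base.mean()) ** 2)), 1e-9)
            expected = None
            for ti, vi in zip(t[t >= 0], values[t >= 0]):
                if abs(vi - base.mean()) > thr:
                    expected = ti * 1000.0
                    break
            assert got == pytest.approx(expected)

    def test_consecutive_sample_requirement_skips_lone_spike(self):
        t = grid()
        values = np.zeros_like(t)
        values[np.argmin(np.abs(t - 0.020))] = 5.0  # single-sample glitch
        values[t >= 0.100] = 5.0
        assert onset_latency(t, values) == pytest.approx(20.0)
        assert onset_latency(t, values, n_consecutive=3) == pytest.approx(100.0)


class TestDisplacements:
    def test_perfect_riding_recovers_platform_displacement(self, base_spec):
        """Head velocity equal to the platform command integrates to 10 deg."""
        trial = make_trial(base_spec)
        a = base_spec.peak_accel
        from tiltpost.design import _eval_profile

        d1, d2 = base_spec.accel_duration, base_spec.plateau_duration
        _, vel, _ = _eval_profile(trial.time, a, a * d1, d1, d2)
        angvel = trial.head_angvel.copy()
        angvel[:, 0] = vel
        riding = make_trial(base_spec, angvel=angvel)
        angular, linear, cop_path = displacements(riding)
        assert angular == pytest.approx(10.0, abs=1e-6)
        assert cop_path == pytest.approx(0.0)

    def test_zero_traces_give_zero_displacements(self, base_spec):
        assert displacements(make_trial(base_spec)) == (0.0, 0.0, 0.0)

    def test_constant_acceleration_double_integral(self, base_spec):
        trial = make_trial(base_spec)
        linacc = trial.head_linacc.copy()
        span = (trial.time >= 0) & (trial.time <= trial.motion_end)
        linacc[span, 0] = 2.0  # m/s^2 over the motion span
        _, linear, _ = displacements(make_trial(base_spec, linacc=linacc))
        T = trial.motion_end
        assert linear == pytest.approx(2.0 * T**2 / 2.0, rel=1e-2)

    def test_cop_path_bounds_net_change(self, base_spec):
        rng = np.random.default_rng(3)
        trial = make_trial(base_spec)
        f = trial.forces
        noisy = make_trial(base_spec)
        forces = type(f)(
            time=f.time,
            F_FL=f.F_FL + rng.normal(0, 1, f.time.shape),
            F_FR=f.F_FR, F_HL=f.F_HL, F_HR=f.F_HR, mass=f.mass,
        )
        import dataclasses

        noisy = dataclasses.replace(trial, forces=forces)
        _, _, path = displacements(noisy)
        cop = compute_cop(forces).ap
        mask = (noisy.time >= 0) & (noisy.time <= noisy.motion_end)
        assert path >= abs(cop[mask][-1] - cop[mask][0]) - 1e-12

    def test_span_outside_trial_is_error(self, base_spec):
        with pytest.raises(ValueError, match="span"):
            displacements(make_trial(base_spec), span=(0.0, 99.0))

    def test_all_study_conditions_integrate_to_10_deg(self):
        """Every study profile's own waveform rides back to D = 10 deg."""
        from tiltpost.design import enumerate_conditions, _eval_profile

        for cond in enumerate_conditions():
            trial = make_trial(cond)
            a = cond.peak_accel
            d1, d2 = cond.accel_duration, cond.plateau_duration
            _, vel, _ = _eval_profile(trial.time, a, a * d1, d1, d2)
            angvel = trial.head_angvel.copy()
            idx = 0 if cond.axis == "pitch" else 1
            angvel[:, idx] = cond.sign * vel
            angular, _, _ = displacements(make_trial(cond, angvel=angvel))
            assert abs(angular) == pytest.approx(10.0, abs=1e-3)


class TestAveraging:
    def test_identical_trials_have_zero_sem(self, base_spec):
        trial = make_trial(base_spec)
        angvel = trial.head_angvel.copy()
        angvel[:, 0] = np.sin(trial.time)
        trials = [make_trial(base_spec, angvel=angvel, trial_id=f"t{i}") for i in range(4)]
        avg = average_condition(trials)
        assert avg.n_trials == 4
        assert np.allclose(avg.mean["angvel"], np.sin(trial.time))
        assert np.allclose(avg.sem["angvel"], 0.0)

    def test_two_trial_hand_values(self, base_spec):
        t0 = make_trial(base_spec)
        angvel2 = t0.head_angvel.copy()
        angvel2[:, 0] = 2.0
        trials = [t0, make_trial(base_spec, angvel=angvel2, trial_id="t1")]
        avg = average_condition(trials)
        assert np.allclose(avg.mean["angvel"], 1.0)
        assert np.allclose(avg.sem["angvel"], 1.0)  # sd = sqrt(2), sem = sd/sqrt(2)

    def test_single_trial_sem_is_zero(self, base_spec):
        avg = average_condition([make_trial(base_spec)])
        assert avg.n_trials == 1
        assert np.all(avg.sem["cop_ap"] == 0.0)

    def test_mixed_conditions_rejected(self, base_spec, roll_spec):
        with pytest.raises(ValueError, match="mix"):
            average_condition([make_trial(base_spec), make_trial(roll_spec)])

    def test_mean_within_3_sem_of_generator_mean(self, base_spec):
        from tiltpost.synth import GeneratorSpec, generate_trial_set

        gen = GeneratorSpec(
            conditions=(base_spec,), n_trials=20, animals={"a": 1.0},
            contamination_rate=0.0, seed=5,
        )
        trials = generate_trial_set(gen)
        avg = average_condition(trials)
        noiseless = generate_trial_set(
            GeneratorSpec(
                conditions=(base_spec,), n_trials=1, animals={"a": 1.0},
                contamination_rate=0.0, seed=5,
                noise_sd={"cop": 0.0, "angvel": 0.0, "linacc": 0.0},
            )
        )
        truth = average_condition(noiseless).mean["angvel"]
        sem = np.maximum(avg.sem["angvel"], 1e-12)
        frac = np.mean(np.abs(avg.mean["angvel"] - truth) <= 3 * sem)
        assert frac >= 0.99


class TestInvertAndPool:
    def _sides(self, spec, n=3):
        pos, neg = [], []
        m = mirror_spec(spec)
        for i in range(n):
            t = make_trial(spec, trial_id=f"p{i}")
            angvel = t.head_angvel.copy()
            angvel[:, 0] = np.sin(t.time) + i
            pos.append(make_trial(spec, angvel=angvel, trial_id=f"p{i}"))
            angvel_m = t.head_angvel.copy()
            angvel_m[:, 0] = -(np.sin(t.time) + i)
            neg.append(make_trial(m, angvel=angvel_m, trial_id=f"n{i}"))
        return pos, neg

    def test_counts_concatenate(self, base_spec):
        pos, neg = self._sides(base_spec)
        pooled = invert_and_pool(pos, neg)
        assert len(pooled) == 6
        assert all(tr.condition.direction == "forward" for tr in pooled)

    def test_mirrored_channels_sign_flipped(self, base_spec):
        pos, neg = self._sides(base_spec)
        pooled = invert_and_pool(pos, neg)
        # the mirrored trials' pitch velocity now matches the reference side
        assert np.allclose(pooled[3].head_angvel[:, 0], pos[0].head_angvel[:, 0])

    def test_cop_consistent_after_mirroring(self, roll_spec):
        from tiltpost.synth import GeneratorSpec, generate_trial_set

        m = mirror_spec(roll_spec)
        gen = GeneratorSpec(
            conditions=(roll_spec, m), n_trials=2, animals={"a": 1.0},
            contamination_rate=0.0, seed=2,
        )
        trials = generate_trial_set(gen)
        pos = [t for t in trials if t.condition.sign > 0]
        neg = [t for t in trials if t.condition.sign < 0]
        pooled = invert_and_pool(pos, neg)
        flipped = pooled[len(pos)]
        orig = neg[0]
        assert np.allclose(
            compute_cop(flipped.forces).lat, -compute_cop(orig.forces).lat
        )

    def test_non_mirror_conditions_rejected(self, base_spec, roll_spec):
        with pytest.raises(ValueError, match="mirror|opposite"):
            invert_and_pool([make_trial(base_spec)] * 2, [make_trial(roll_spec)] * 2)

    def test_empty_side_warns_and_passes_through(self, base_spec):
        with pytest.warns(UserWarning, match="empty"):
            pooled = invert_and_pool([make_trial(base_spec)], [])
        assert len(pooled) == 1
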