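"""Initial pose, strapdown integration and the roll-constraint correction."""

import dataclasses

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.spatial.transform import Rotation

from swimvel import quat
from swimvel.kinematics import detect_cycles
from swimvel.orientation import (FORWARD, OrientationSeries,
                                 correct_orientation_series,
                                 corrective_quaternion,
                                 drift_correction_for_cycle,
                                 initial_orientation, principal_roll_axis,
                                 rotate_to_global, strapdown_orientation,
                                 update_orientation)
from swimvel.simulator import scenario, simulate_swim

G = 9.81


class TestInitialOrientation:
    def test_upright_sensor_gives_identity(self):
        pose = initial_orientation(np.array([0.0, 0.0, G]))
        assert pose.theta0 == pytest.approx(0.0)
        assert np.allclose(pose.q0, quat.identity(), atol=1e-9)

    def test_quarter_turn_about_x(self):
        pose = initial_orientation(np.array([0.0, G, 0.0]))
        assert pose.theta0 == pytest.approx(np.pi / 2, abs=1e-9)
        assert np.allclose(np.abs(pose.u0), [1.0, 0.0, 0.0], atol=1e-9)
        up = quat.rotate(pose.q0, np.array([0.0, 1.0, 0.0]))
        assert np.allclose(up, [0.0, 0.0, 1.0], atol=1e-6)

    def test_axis_is_horizontal_and_angle_in_range(self, rng):
        for _ in range(25):
            a = rng.standard_normal(3)
            a = a / np.linalg.norm(a) * G
            pose = initial_orientation(a)
            assert abs(pose.u0[2]) < 1e-9
            assert 0.0 <= pose.theta0 <= np.pi

    def test_recovers_vertical_from_random_true_orientation(self, rng):
        for _ in range(25):
            q_true = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
            # a static sensor reads the gravity reaction, global +Z in its frame
            a0 = q_true.inv().apply([0.0, 0.0, G])
            pose = initial_orientation(a0)
            assert np.allclose(quat.rotate(pose.q0, a0 / G), [0, 0, 1], atol=1e-6)

    def test_rejects_non_static_magnitude(self):
        with pytest.raises(ValueError):
            initial_orientation(np.array([0.0, 0.0, G * 1.2]))
        with pytest.raises(ValueError):
            initial_orientation(np.zeros(3))


class TestStrapdown:
    def test_zero_rate_is_identity_update(self):
        q = quat.from_axis_angle(np.array([0.0, 1.0, 0.0]), 0.7)
        assert np.allclose(update_orientation(q, np.zeros(3), 500.0), q, atol=1e-12)

    def test_constant_rate_closed_form(self):
        q = quat.identity()
        omega = np.array([0.0, 0.0, np.pi / 2])
        for _ in range(500):
            q = update_orientation(q, omega, 500.0)
        expected = quat.from_axis_angle(np.array([0.0, 0.0, 1.0]), np.pi / 2)
        assert quat.angle_between(q, expected) < 1e-6

    def test_piecewise_constant_matches_matrix_exponential(self, rng):
        f = 200.0
        omegas = rng.uniform(-2.0, 2.0, (50, 3))
        q = quat.identity()
        R = np.eye(3)
        for w in omegas:
            q = update_orientation(q, w, f)
            wx = np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]])
            R = R @ expm(wx / f)   # body-frame composition: right-multiply
            assert np.allclose(quat.to_matrix(q), R, atol=1e-6)

    def test_series_matches_stepwise_updates(self, rng):
        f = 100.0
        gyro = rng.uniform(-1.0, 1.0, (40, 3))
        gyro[0] = 0.0
        q0 = quat.normalize(rng.standard_normal(4))
        series = strapdown_orientation(gyro, f, q0)
        q = q0
        for t in range(1, len(gyro)):
            q = update_orientation(q, gyro[t], f)
            assert np.allclose(series[t], q, atol=1e-9)

    def test_unit_norm_throughout(self, rng):
        gyro = rng.uniform(-3, 3, (2000, 3))
        series = strapdown_orientation(gyro, 500.0, quat.identity())
        assert np.allclose(np.linalg.norm(series, axis=1), 1.0, atol=1e-9)

    def test_halving_step_changes_result_little(self):
        # a fixed continuous omega(t), integrated at f and 2f
        f = 250.0
        t1 = np.arange(int(2 * f)) / f
        t2 = np.arange(int(2 * 2 * f)) / (2 * f)

        def omega(t):
            return np.stack([np.sin(2 * t), 0.5 * np.cos(3 * t), 0.2 * np.ones_like(t)], axis=1)

        qa = strapdown_orientation(omega(t1), f, quat.identity())[-1]
        qb = strapdown_orientation(omega(t2), 2 * f, quat.identity())[-1]
        assert quat.angle_between(qa, qb) < 5.0 / f


class TestRotateToGlobal:
    def test_identity_and_quarter_turn(self):
        assert np.allclose(rotate_to_global(quat.identity(), [1.0, 2.0, 3.0]), [1, 2, 3])
        q = quat.from_axis_angle(np.array([0.0, 0.0, 1.0]), np.pi / 2)
        assert np.allclose(rotate_to_global(q, [1.0, 0.0, 0.0]), [0, 1, 0], atol=1e-9)


class TestPrincipalRollAxis:
    def test_exact_forward_cloud(self):
        w = np.outer(np.sin(np.linspace(0, 6, 100)), [0.0, 2.0, 0.0])
        assert np.allclose(principal_roll_axis(w), FORWARD, atol=1e-12)

    def test_tilted_axis_with_orthogonal_noise(self, rng):
        tilt = np.deg2rad(10.0)
        axis = np.array([0.0, np.cos(tilt), np.sin(tilt)])
        amp = np.sin(np.linspace(0, 20, 400))
        w = np.outer(amp, axis) + 0.01 * rng.standard_normal((400, 3))
        p = principal_roll_axis(w)
        ang = np.degrees(np.arccos(np.clip(abs(p @ axis), -1, 1)))
        assert ang < 0.5

    def test_matches_covariance_eigvector_oracle(self, rng):
        for _ in range(20):
            w = rng.standard_normal((rng.integers(3, 60), 3)) * [1.0, 3.0, 0.5]
            p = principal_roll_axis(w)
            c = np.cov((w - w.mean(axis=0)).T)
            evals, evecs = np.linalg.eigh(c)
            e = evecs[:, -1]
            if e @ FORWARD < 0:
                e = -e
            assert np.allclose(p, e, atol=1e-9) or np.allclose(p, -e, atol=1e-9)

    def test_degenerate_cloud_rejected(self):
        with pytest.raises(ValueError):
            principal_roll_axis(np.zeros((50, 3)))
        with pytest.raises(ValueError):
            principal_roll_axis(np.ones((2, 3)))


class TestDriftCorrection:
    def test_correction_rotates_axis_onto_forward(self, rng):
        for _ in range(20):
            p = rng.standard_normal(3)
            p /= np.linalg.norm(p)
            if p @ FORWARD < 0:
                p = -p
            corr = drift_correction_for_cycle(p, n_samples=100)
            assert abs(np.linalg.norm(corr.u_axis) - 1.0) < 1e-9
            assert abs(corr.u_axis @ FORWARD) < 1e-9
            assert 0.0 <= corr.delta_theta <= np.pi
            q_end = corrective_quaternion(corr, corr.n_samples)
            assert np.allclose(quat.rotate(q_end, p), FORWARD, atol=1e-9)

    def test_ramp_is_zero_at_start_and_linear(self):
        corr = drift_correction_for_cycle(
            np.array([np.sin(0.2), np.cos(0.2), 0.0]), n_samples=11
        )
        assert np.allclose(corrective_quaternion(corr, 1), quat.identity(), atol=1e-12)
        _, mid = quat.to_axis_angle(corrective_quaternion(corr, 6))
        assert mid == pytest.approx(corr.delta_theta / 2, abs=1e-9)


def _pure_roll_recording():
    """20 s of exact full-amplitude roll about the forward axis."""
    from swimvel.kinematics import ImuRecording

    f, fc = 500.0, 0.75
    t = np.arange(int(20 * f)) / f
    roll_rate = np.deg2rad(45) * 2 * np.pi * fc * np.cos(2 * np.pi * fc * t)
    gyro = np.column_stack([np.zeros_like(t), roll_rate, np.zeros_like(t)])
    accel = np.zeros((len(t), 3))
    accel[:, 2] = G
    return ImuRecording(t=t, accel=accel, gyro=gyro, f=f)


class TestCorrectOrientationSeries:
    def test_noop_on_drift_free_roll(self):
        rec = _pure_roll_recording()
        series = OrientationSeries(q=strapdown_orientation(rec.gyro, rec.f, quat.identity()), f=rec.f)
        cycles = detect_cycles(rec, series)
        out = correct_orientation_series(series, rec.gyro, cycles.boundaries)
        # angle_between has an arccos resolution floor of ~3e-8 at zero
        assert np.max(quat.angle_between(out.q, series.q)) < 1e-6
        assert all(c.delta_theta < 1e-9 for c in out.corrections)

    @staticmethod
    def _biased_run(bias):
        cfg = dataclasses.replace(
            scenario("elite_t3", seed=3),
            gyro_noise_sd=0.0, accel_noise_sd=0.0, pitch_yaw_jitter=0.0,
            gyro_bias=bias,
        )
        truth, rec, _ = simulate_swim(cfg)
        pose = initial_orientation(rec.accel[: int(0.5 * rec.f)].mean(axis=0))
        raw = OrientationSeries(q=strapdown_orientation(rec.gyro, rec.f, pose.q0), f=rec.f)
        cycles = detect_cycles(rec, raw)
        return truth, rec, raw, cycles

    def test_bias_injection_halves_terminal_error(self):
        bias = (np.deg2rad(0.5), 0.0, 0.0)
        truth, rec, raw, cycles = self._biased_run(bias)
        corrected = correct_orientation_series(raw, rec.gyro, cycles.boundaries)
        e_raw = quat.angle_between(raw.q[-1], truth.orientation[-1])
        e_cor = quat.angle_between(corrected.q[-1], truth.orientation[-1])
        assert e_cor <= 0.5 * e_raw

    def test_contraction_second_application_smaller(self):
        bias = (np.deg2rad(0.3), 0.0, np.deg2rad(0.3))
        _, rec, raw, cycles = self._biased_run(bias)
        once = correct_orientation_series(raw, rec.gyro, cycles.boundaries)
        twice = correct_orientation_series(once, rec.gyro, cycles.boundaries)
        first_mag = np.max(quat.angle_between(raw.q, once.q))
        second_mag = np.max(quat.angle_between(once.q, twice.q))
        assert second_mag < first_mag

    def test_output_unit_norm(self):
        _, rec, raw, cycles = self._biased_run((np.deg2rad(0.5), 0.0, 0.0))
        out = correct_orientation_series(raw, rec.gyro, cycles.boundaries)
        assert np.allclose(np.linalg.norm(out.q, axis=1), 1.0, atol=1e-9)

    def test_length_mismatch_rejected(self):
        rec = _pure_roll_recording()
        series = OrientationSeries(q=strapdown_orientation(rec.gyro, rec.f, quat.identity()), f=rec.f)
        with pytest.raises(ValueError):
            correct_orientation_series(series, rec.gyro[:-5], np.array([0, 100]))
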