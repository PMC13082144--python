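"""Error-state filter core: predict, implicit update, observability, gating."""

import numpy as np
import pytest

from majic import rotations as rot
from majic.filters import (
    NoiseConfig,
    RelativeFilterState,
    gate_sensors,
    kalman_gain,
    measurement_jacobian,
    measurement_residual,
    observability,
    predict,
    run_relative_filter,
    update,
)
from majic import pipeline


def make_state(rng, p_scale=0.01):
    A = rng.normal(size=(6, 6))
    return RelativeFilterState(
        R_WJ=rot.random_rotation(rng),
        R_WK=rot.random_rotation(rng),
        P=p_scale * (A @ A.T + np.eye(6)),
    )


class TestPredict:
    def test_zero_gyro_grows_p_by_q_exactly(self, rng):
        noise = NoiseConfig()
        s = make_state(rng)
        out = predict(s, np.zeros(3), np.zeros(3), 0.01, noise)
        np.testing.assert_allclose(out.R_WJ, s.R_WJ)
        np.testing.assert_allclose(out.R_WK, s.R_WK)
        np.testing.assert_allclose(
            out.P, s.P + noise.gyro_noise**2 * 0.01 * np.eye(6), atol=1e-15
        )

    def test_constant_rate_integrates_to_quarter_turn(self):
        noise = NoiseConfig()
        s = RelativeFilterState(np.eye(3), np.eye(3), np.eye(6))
        w = np.array([0, 0, 1.0])
        n, dt = 500, (np.pi / 2) / 500
        for _ in range(n):
            s = predict(s, w, np.zeros(3), dt, noise)
        np.testing.assert_allclose(s.R_WJ, rot.exp_map([0, 0, np.pi / 2]), atol=1e-6)
        np.testing.assert_allclose(s.R_WK, np.eye(3), atol=1e-12)

    def test_trace_strictly_increases_without_updates(self, rng):
        noise = NoiseConfig()
        s = make_state(rng)
        traces = [np.trace(s.P)]
        for _ in range(10):
            s = predict(s, rng.normal(size=3), rng.normal(size=3), 0.01, noise)
            traces.append(np.trace(s.P))
        assert np.all(np.diff(traces) > 0)

    def test_nonpositive_dt_rejected(self, rng):
        with pytest.raises(ValueError, match="dt"):
            predict(make_state(rng), np.zeros(3), np.zeros(3), 0.0, NoiseConfig())


class TestResidual:
    def test_consistent_identity_is_zero(self):
        s = RelativeFilterState(np.eye(3), np.eye(3), np.eye(6))
        y = [np.array([1.0, 2.0, 3.0])]
        np.testing.assert_allclose(measurement_residual(s, y, y), np.zeros(3))

    def test_mismatched_counts_rejected(self):
        s = RelativeFilterState(np.eye(3), np.eye(3), np.eye(6))
        with pytest.raises(ValueError, match="sensor counts"):
            measurement_residual(s, [np.zeros(3)], [np.zeros(3), np.zeros(3)])

    def test_zero_at_ground_truth_on_noiseless_simulation(self, rich_sim):
        """With exact orientations and exact joint-center projections the
        implicit measurement vanishes to machine precision."""
        from majic.virtual_sensor import joint_center_acceleration

        joint, sj, sk = "knee", "thigh_imu", "shank_imu"
        aJ = joint_center_acceleration(
            rich_sim.streams[sj].accel, rich_sim.streams[sj].gyro,
            rich_sim.sensor_alpha(sj), rich_sim.mounts[sj][joint].r,
        )
        aK = joint_center_acceleration(
            rich_sim.streams[sk].accel, rich_sim.streams[sk].gyro,
            rich_sim.sensor_alpha(sk), rich_sim.mounts[sk][joint].r,
        )
        RJ = np.einsum(
            "nij,jk->nik",
            rich_sim.truth_global["thigh"].as_matrices(),
            rich_sim.sensor_rotation[sj],
        )
        RK = np.einsum(
            "nij,jk->nik",
            rich_sim.truth_global["shank"].as_matrices(),
            rich_sim.sensor_rotation[sk],
        )
        for k in range(0, len(rich_sim.time), 50):
            s = RelativeFilterState(RJ[k], RK[k], np.eye(6))
            h = measurement_residual(s, [aJ[k]], [aK[k]])
            assert np.linalg.norm(h) <= 1e-9


class TestJacobian:
    def test_zero_readings_give_zero_matrix(self, rng):
        s = make_state(rng)
        H = measurement_jacobian(s, [np.zeros(3)], [np.zeros(3)])
        np.testing.assert_allclose(H, np.zeros((3, 6)))

    def test_single_sensor_rank_deficient(self, rng):
        s = make_state(rng)
        H = measurement_jacobian(s, [rng.normal(size=3)], [rng.normal(size=3)])
        assert np.linalg.matrix_rank(H, tol=1e-10) <= 4  # each skew block has rank 2

    def test_matches_finite_differences(self, rng):
        """Central finite differences of the residual under exponential-map
        perturbations reproduce the analytic Jacobian (>=100 random cases)."""
        eps = 1e-6
        for _ in range(100):
            s = make_state(rng)
            n_sensors = rng.integers(1, 3)
            yJ = [rng.normal(size=3) for _ in range(n_sensors)]
            yK = [rng.normal(size=3) for _ in range(n_sensors)]
            H = measurement_jacobian(s, yJ, yK)
            H_fd = np.zeros_like(H)
            for i in range(6):
                e = np.zeros(6)
                e[i] = eps
                sp = RelativeFilterState(
                    s.R_WJ @ rot.exp_map(e[:3]), s.R_WK @ rot.exp_map(e[3:]), s.P
                )
                sm = RelativeFilterState(
                    s.R_WJ @ rot.exp_map(-e[:3]), s.R_WK @ rot.exp_map(-e[3:]), s.P
                )
                H_fd[:, i] = (
                    measurement_residual(sp, yJ, yK) - measurement_residual(sm, yJ, yK)
                ) / (2 * eps)
            assert np.abs(H - H_fd).max() <= 1e-5

    def test_perturbation_direction_matches_jacobian_column(self, rng):
        s = make_state(rng)
        yJ, yK = [rng.normal(size=3)], [rng.normal(size=3)]
        eta = 1e-4 * rng.normal(size=3)
        sp = RelativeFilterState(s.R_WJ @ rot.exp_map(eta), s.R_WK, s.P)
        h0 = measurement_residual(s, yJ, yK)
        h1 = measurement_residual(sp, yJ, yK)
        H = measurement_jacobian(s, yJ, yK)
        np.testing.assert_allclose(h1 - h0, H[:, :3] @ eta, atol=1e-7)


class TestKalmanGain:
    def test_zero_jacobian_gives_zero_gain(self, rng):
        K = kalman_gain(np.eye(6), np.zeros((3, 6)), np.eye(3))
        np.testing.assert_allclose(K, np.zeros((6, 3)))

    def test_gain_vanishes_monotonically_with_noise(self, rng):
        P = np.eye(6)
        H = rng.normal(size=(6, 6))
        norms = [
            np.linalg.norm(kalman_gain(P, H, lam * np.eye(6)))
            for lam in [1.0, 10.0, 100.0, 1e4, 1e6]
        ]
        assert all(a > b for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-4

    def test_scalar_closed_form(self):
        p, h, r = 0.7, 1.3, 0.2
        K = kalman_gain(
            np.diag([p, 0, 0, 0, 0, 0]),
            np.array([[h, 0, 0, 0, 0, 0]]),
            np.array([[r]]),
        )
        assert np.isclose(K[0, 0], p * h / (h**2 * p + r))


class TestUpdate:
    def test_zero_residual_keeps_orientations_and_shrinks_p(self, rng):
        s = make_state(rng)
        yJ, yK = [rng.normal(size=3)], [rng.normal(size=3)]
        H = measurement_jacobian(s, yJ, yK)
        out = update(s, np.zeros(3), H, 0.1 * np.eye(3))
        np.testing.assert_allclose(out.R_WJ, s.R_WJ, atol=1e-12)
        np.testing.assert_allclose(out.R_WK, s.R_WK, atol=1e-12)
        assert np.trace(out.P) < np.trace(s.P)

    def test_convergence_from_perturbed_initialization(self, rng):
        """Noiseless consistent readings from two rotating reference vectors
        pull a perturbed state back: ||h|| < 1e-6 within 100 steps."""
        noise = NoiseConfig()
        R_WJ_true = rot.random_rotation(rng)
        R_WK_true = rot.random_rotation(rng)
        s = RelativeFilterState(
            R_WJ_true @ rot.exp_map(0.2 * rng.normal(size=3)),
            R_WK_true @ rot.exp_map(0.2 * rng.normal(size=3)),
            0.1 * np.eye(6),
        )
        Rm = 1e-9 * np.eye(6)  # readings are exactly consistent
        h = None
        for k in range(100):
            t = 0.01 * k
            v1 = np.array([np.cos(3 * t), np.sin(3 * t), 0.5])
            v2 = np.array([0.2, np.cos(2 * t), np.sin(2 * t)])
            yJ = [R_WJ_true.T @ v1, R_WJ_true.T @ v2]
            yK = [R_WK_true.T @ v1, R_WK_true.T @ v2]
            s = predict(s, np.zeros(3), np.zeros(3), 0.01, noise)
            h = measurement_residual(s, yJ, yK)
            s = update(s, h, measurement_jacobian(s, yJ, yK), Rm)
        assert np.linalg.norm(h) < 1e-6

    def test_covariance_stays_symmetric_psd_under_random_updates(self, rng):
        s = make_state(rng)
        for _ in range(10_000):
            yJ = [rng.normal(size=3)]
            yK = [rng.normal(size=3)]
            H = measurement_jacobian(s, yJ, yK)
            h = measurement_residual(s, yJ, yK)
            s = update(s, h, H, 0.5 * np.eye(3))
            s = predict(s, rng.normal(size=3), rng.normal(size=3), 0.01, NoiseConfig())
        np.testing.assert_allclose(s.P, s.P.T, atol=1e-12)
        assert np.linalg.eigvalsh(s.P).min() >= -1e-12


class TestObservability:
    def test_zero_acceleration_gives_zero(self):
        t = np.arange(100) / 100.0
        o = observability(np.zeros((100, 3)), np.zeros((100, 3)), t)
        np.testing.assert_allclose(o, 0.0)

    def test_static_segment_unobservable(self):
        t = np.arange(100) / 100.0
        a = np.tile([0, 0, 9.81], (100, 1))
        o = observability(a, np.zeros((100, 3)), t)
        np.testing.assert_allclose(o, 0.0, atol=1e-9)

    def test_circular_sweep_closed_form(self):
        # a(t) = A [cos Wt, sin Wt, 0], omega = 0  ->  o = A^2 W
        A, W, fs = 4.0, 2 * np.pi * 1.0, 100.0
        t = np.arange(int(5 * fs)) / fs
        a = A * np.column_stack([np.cos(W * t), np.sin(W * t), np.zeros_like(t)])
        o = observability(a, np.zeros((len(t), 3)), t)
        expected = A**2 * W
        assert np.abs(o[5:-5] - expected).max() <= 0.01 * expected


class TestGate:
    @pytest.mark.parametrize(
        "o,expected",
        [
            (100.0, {"accel", "mag"}),
            (200.0, {"accel"}),
            (150.0, {"accel"}),  # strict "drops below"
        ],
    )
    def test_threshold_150(self, o, expected):
        assert gate_sensors(o, 150.0) == frozenset(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            gate_sensors(-1.0, 150.0)
        with pytest.raises(ValueError):
            gate_sensors(10.0, 0.0)


class TestRunRelativeFilter:
    def test_mode_collapse_threshold_zero_equals_magoff(self, quasi_sim_noisy):
        sim = quasi_sim_noisy
        args = (
            sim.streams["pelvis_imu"], sim.streams["thigh_imu"],
            sim.mounts["pelvis_imu"]["hip"], sim.mounts["thigh_imu"]["hip"],
        )
        off = run_relative_filter(*args, method="magoff")
        adaptive = run_relative_filter(*args, method="majic", threshold=1e-12)
        assert np.array_equal(off.orientations.quat, adaptive.orientations.quat)

    def test_mode_collapse_threshold_inf_equals_magon(self, quasi_sim_noisy):
        sim = quasi_sim_noisy
        args = (
            sim.streams["pelvis_imu"], sim.streams["thigh_imu"],
            sim.mounts["pelvis_imu"]["hip"], sim.mounts["thigh_imu"]["hip"],
        )
        on = run_relative_filter(*args, method="magon")
        adaptive = run_relative_filter(*args, method="majic", threshold=np.inf)
        assert np.array_equal(on.orientations.quat, adaptive.orientations.quat)

    def test_gauge_invariance_under_common_left_rotation(self, rich_sim_noisy, rng):
        """Relative filters use no world reference: rotating both initial
        orientations by a common L leaves the emitted R_JK unchanged."""
        sim = rich_sim_noisy
        args = (
            sim.streams["thigh_imu"], sim.streams["shank_imu"],
            sim.mounts["thigh_imu"]["knee"], sim.mounts["shank_imu"]["knee"],
        )
        R0J = rot.random_rotation(rng)
        R0K = rot.random_rotation(rng)
        L = rot.random_rotation(rng)
        a = run_relative_filter(*args, method="majic", init=(R0J, R0K))
        b = run_relative_filter(*args, method="majic", init=(L @ R0J, L @ R0K))
        np.testing.assert_allclose(
            a.orientations.quat, b.orientations.quat, atol=1e-7
        )

    def test_misaligned_timestamps_rejected(self, quasi_sim_noisy):
        from dataclasses import replace
        sim = quasi_sim_noisy
        sK = sim.streams["thigh_imu"]
        shifted = replace(sK, time=sK.time + 0.005)  # half a sample at 100 Hz
        with pytest.raises(ValueError, match="misaligned"):
            run_relative_filter(
                sim.streams["pelvis_imu"], shifted,
                sim.mounts["pelvis_imu"]["hip"], sim.mounts["thigh_imu"]["hip"],
            )

    def test_noiseless_rich_motion_tracks_truth(self, rich_sim):
        """All relative methods stay under 0.5 deg error on noiseless data."""
        from majic.evaluation import rmse_angle

        for method in ("magoff", "magon", "majic"):
            est, _ = pipeline.fit_joint(rich_sim, "knee", method, init_truth=True)
            assert rmse_angle(est, rich_sim.truth_relative["knee"]) < 0.5

    def test_covariance_healthy_along_the_run(self, rich_sim_noisy):
        sim = rich_sim_noisy
        out = run_relative_filter(
            sim.streams["thigh_imu"], sim.streams["shank_imu"],
            sim.mounts["thigh_imu"]["knee"], sim.mounts["shank_imu"]["knee"],
            method="majic",
        )
        assert np.all(out.P_trace > 0)
        assert np.all(np.isfinite(out.P_trace))
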