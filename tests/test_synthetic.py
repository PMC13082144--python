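"""Simulator: kinematic identities, consistency oracles, determinism."""

import numpy as np
import pytest

from majic.filters import observability
from majic.synthetic import (
    BaseTrajectory,
    ChainSpec,
    FieldModel,
    JointTrajectory,
    SegmentSpec,
    SensorSpec,
    build_scenario,
    scenario_library,
    simulate,
)
from majic.virtual_sensor import joint_center_acceleration


def two_link(joint_traj, base=None, rate=100.0, duration=5.0, seed=0, sensors=None):
    chain = ChainSpec(
        segments=(SegmentSpec("upper", 0.3), SegmentSpec("lower", 0.35)),
        joints=(("elbow", joint_traj),),
        base=base or BaseTrajectory(),
        rate=rate, duration=duration, seed=seed,
    )
    if sensors is None:
        sensors = (
            SensorSpec("upper_imu", "upper", position=(0.15, 0.02, 0.0)),
            SensorSpec("lower_imu", "lower", position=(0.2, 0.0, 0.03)),
        )
    return chain, sensors


class TestKinematicIdentities:
    def test_static_chain(self):
        chain, sensors = two_link(JointTrajectory())  # zero amplitudes
        sim = simulate(chain, FieldModel(), sensors)
        for name, stream in sim.streams.items():
            np.testing.assert_allclose(stream.gyro, 0.0, atol=1e-12)
            np.testing.assert_allclose(
                stream.accel, np.tile([0, 0, 9.81], (len(stream), 1)), atol=1e-9
            )
        aa = sim.truth_relative["elbow"].angle_axis()
        np.testing.assert_allclose(aa - aa[0], 0.0, atol=1e-12)

    def test_single_hinge_matches_prescribed_sinusoid(self):
        A, f = 0.6, 1.0
        traj = JointTrajectory(amplitude=(0, 0, A), frequency=(1, 1, f))
        chain, sensors = two_link(traj)
        sim = simulate(chain, FieldModel(), sensors)
        aa = sim.truth_relative["elbow"].angle_axis()
        expected = A * np.sin(2 * np.pi * f * sim.time)
        np.testing.assert_allclose(aa[:, 2], expected, atol=1e-12)
        np.testing.assert_allclose(aa[:, :2], 0.0, atol=1e-12)

    def test_world_acceleration_matches_position_second_derivative(self):
        """4th-order finite differences of emitted sensor world positions
        reproduce the emitted world accelerations (independent oracle)."""
        traj = JointTrajectory(amplitude=(0.2, 0.5, 0.1), frequency=(1, 1, 2),
                               phase=(0.3, 0.0, 1.0))
        base = BaseTrajectory(
            orientation=JointTrajectory(amplitude=(0.1, 0.05, 0.1), frequency=(1, 1, 1)),
            position_amplitude=(0.03, 0.02, 0.04), position_frequency=(1, 2, 1),
        )
        chain, sensors = two_link(traj, base=base, rate=500.0, duration=2.0)
        sim = simulate(chain, FieldModel(), sensors)
        dt = 1.0 / 500.0
        for name in sim.streams:
            p = sim.sensor_world_pos[name]
            acc = sim.sensor_world_acc[name]
            num = (
                -p[4:] + 16 * p[3:-1] - 30 * p[2:-2] + 16 * p[1:-3] - p[:-4]
            ) / (12 * dt**2)
            assert np.abs(num - acc[2:-2]).max() < 1e-4

    def test_gravity_recovered_in_world_frame(self):
        """Over whole periods, the world-frame average of noiseless accel
        equals gravity: bounded displacement contributes nothing."""
        traj = JointTrajectory(amplitude=(0.1, 0.4, 0.2), frequency=(1, 1, 1))
        chain, sensors = two_link(traj, duration=4.0)
        sim = simulate(chain, FieldModel(), sensors)
        C = sim.sensor_rotation["lower_imu"]
        Rws = sim.truth_global["lower"].as_matrices()
        R_sen = np.einsum("nij,jk->nik", Rws, C)
        world = np.einsum("nij,nj->ni", R_sen, sim.streams["lower_imu"].accel)
        mean = world[:-1].mean(axis=0)  # drop duplicated period endpoint
        np.testing.assert_allclose(mean, [0, 0, 9.81], atol=1e-6)

    def test_virtual_projection_closes_loop_with_truth(self):
        """Joint-center acceleration projected from either side equals the
        exact joint specific force (offset invariance across segments)."""
        traj = JointTrajectory(amplitude=(0.2, 0.5, 0.1), frequency=(1, 1, 1))
        chain, sensors = two_link(traj)
        sim = simulate(chain, FieldModel(), sensors)
        for name, seg in (("upper_imu", "upper"), ("lower_imu", "lower")):
            st = sim.streams[name]
            a_hat = joint_center_acceleration(
                st.accel, st.gyro, sim.sensor_alpha(name), sim.mounts[name]["elbow"].r
            )
            expected = sim.joint_specific_force("elbow", seg) @ sim.sensor_rotation[name]
            assert np.abs(a_hat - expected).max() < 1e-6


class TestValidation:
    def test_rate_invariant_names_field(self):
        with pytest.raises(ValueError, match="rate"):
            ChainSpec(
                segments=(SegmentSpec("a", 0.3), SegmentSpec("b", 0.3)),
                joints=(("j", JointTrajectory(amplitude=(0, 0, 0.3),
                                              frequency=(1, 1, 10))),),
                rate=100.0, duration=1.0,
            )

    def test_duration_invariant_names_field(self):
        with pytest.raises(ValueError, match="duration"):
            ChainSpec(
                segments=(SegmentSpec("a", 0.3), SegmentSpec("b", 0.3)),
                joints=(("j", JointTrajectory()),),
                duration=0.0,
            )

    def test_unknown_segment_rejected(self):
        chain, _ = two_link(JointTrajectory())
        with pytest.raises(ValueError, match="unknown segment"):
            simulate(chain, FieldModel(), (SensorSpec("x", "nope"),))

    def test_dipole_field_nonzero_check(self):
        fm = FieldModel((1.0, 0, 0), ())
        B = fm.field(np.zeros((5, 3)))
        np.testing.assert_allclose(B, np.tile([1.0, 0, 0], (5, 1)))


class TestScenarios:
    def test_unknown_preset_lists_available(self):
        with pytest.raises(ValueError, match="quasi_static"):
            build_scenario("nope")

    def test_determinism_same_seed_bit_identical(self, scenarios):
        a = scenarios["quasi_static"].simulate(duration=2.0)
        b = scenarios["quasi_static"].simulate(duration=2.0)
        for name in a.streams:
            assert np.array_equal(a.streams[name].gyro, b.streams[name].gyro)
            assert np.array_equal(a.streams[name].accel, b.streams[name].accel)
            assert np.array_equal(a.streams[name].mag, b.streams[name].mag)

    def test_different_seed_differs(self, scenarios):
        a = scenarios["quasi_static"].simulate(duration=2.0, seed=1)
        b = scenarios["quasi_static"].simulate(duration=2.0, seed=2)
        assert not np.array_equal(
            a.streams["thigh_imu"].gyro, b.streams["thigh_imu"].gyro
        )

    @staticmethod
    def _joint_observability(sim, joint, sensor_J, sensor_K):
        o = []
        for name in (sensor_J, sensor_K):
            st = sim.streams[name]
            a_hat = joint_center_acceleration(
                st.accel, st.gyro, sim.sensor_alpha(name), sim.mounts[name][joint].r
            )
            o.append(observability(a_hat, st.gyro, sim.time, smooth_cutoff=10.0))
        return np.minimum(*o)

    def test_quasi_static_observability_regime(self, quasi_sim_noisy):
        o = self._joint_observability(quasi_sim_noisy, "hip", "pelvis_imu", "thigh_imu")
        assert (o < 150.0).mean() > 0.95

    def test_rich_gait_distal_observability_regime(self, rich_sim_noisy):
        o = self._joint_observability(rich_sim_noisy, "knee", "thigh_imu", "shank_imu")
        assert (o >= 150.0).mean() >= 0.25
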