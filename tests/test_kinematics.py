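"""Quaternion calibration, Euler angles, joint angles, events, parameters."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gaitspm import emg, kinematics, synthio

FS = 75.0


def zrot_stream(z_deg, fs=FS, site=""):
    half = np.radians(np.asarray(z_deg, dtype=float)) / 2.0
    q = np.column_stack(
        [np.cos(half), np.zeros_like(half), np.zeros_like(half), np.sin(half)]
    )
    return kinematics.QuaternionStream(quats=q, fs=fs, sensor_site=site)


class TestCalibrateNeutral:
    def test_identity_stream(self):
        ref = kinematics.calibrate_neutral(zrot_stream(np.zeros(800)), 10.0)
        assert np.allclose(ref, [1, 0, 0, 0], atol=1e-9)

    def test_constant_rotation_reference(self):
        stream = zrot_stream(np.full(800, 30.0))
        ref = kinematics.calibrate_neutral(stream, 10.0)
        rel = kinematics.relative_orientation(stream, ref)
        assert np.allclose(kinematics.sagittal_angle(rel), 0.0, atol=1e-6)

    def test_noisy_reference_close_to_truth(self, rng):
        angles = 20.0 + rng.normal(0, 1.0, 800)
        ref = kinematics.calibrate_neutral(zrot_stream(angles), 10.0)
        ref_angle = np.degrees(
            Rotation.from_quat(np.asarray(ref)[[1, 2, 3, 0]]).as_rotvec()[2]
        )
        assert abs(ref_angle - 20.0) < 0.5

    def test_motion_rejected(self):
        drifting = np.linspace(0, 90, 800)  # 9 deg/s drift
        with pytest.raises(ValueError):
            kinematics.calibrate_neutral(zrot_stream(drifting), 10.0)


class TestToEuler:
    def test_pure_z_rotation(self):
        out = kinematics.to_euler(zrot_stream([30.0]))
        assert out[0, 0] == pytest.approx(30.0, abs=1e-9)

    def test_z_rotations_additive(self):
        r = Rotation.from_euler("z", 10, degrees=True) * Rotation.from_euler(
            "z", 20, degrees=True
        )
        q = r.as_quat()[[3, 0, 1, 2]]
        stream = kinematics.QuaternionStream(quats=q[None, :], fs=FS)
        assert kinematics.to_euler(stream)[0, 0] == pytest.approx(30.0, abs=1e-9)

    def test_matches_rotation_matrix_oracle(self, rng):
        for axis in "xyz":
            angles = rng.uniform(-80, 80, 50)
            rots = Rotation.from_euler(axis, angles[:, None], degrees=True)
            q = rots.as_quat()[:, [3, 0, 1, 2]]
            stream = kinematics.QuaternionStream(quats=q, fs=FS)
            euler = kinematics.to_euler(stream)
            expected = rots.as_euler("ZYX", degrees=True)
            assert np.max(np.abs(euler - expected)) < 1e-6

    def test_gimbal_warning(self):
        r = Rotation.from_euler("ZYX", [0, 88, 0], degrees=True)
        q = r.as_quat()[[3, 0, 1, 2]]
        with pytest.warns(UserWarning):
            kinematics.to_euler(kinematics.QuaternionStream(quats=q[None, :], fs=FS))


class TestJointAngle:
    def test_equal_segments_zero(self):
        z = np.linspace(0, 40, 400)
        track = kinematics.joint_angle(z, z, FS, "knee")
        assert np.allclose(track.angle_deg, 0.0, atol=1e-9)

    def test_sign_conventions(self):
        prox = np.zeros(400)
        dist = np.full(400, 10.0)
        hip = kinematics.joint_angle(dist, prox, FS, "hip")
        knee = kinematics.joint_angle(dist, prox, FS, "knee")
        assert hip.angle_deg[200] == pytest.approx(10.0, abs=1e-6)
        assert knee.angle_deg[200] == pytest.approx(-10.0, abs=1e-6)

    def test_step_response_no_large_overshoot(self):
        dist = np.concatenate([np.zeros(400), np.full(400, 10.0)])
        track = kinematics.joint_angle(dist, np.zeros(800), FS, "hip")
        assert track.angle_deg.max() < 11.5  # < 15 % overshoot

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            kinematics.joint_angle(np.zeros(10), np.zeros(11), FS, "hip")

    def test_roundtrip_through_generator(self):
        wf = synthio.knee_like_waveform(53.7)
        plan = synthio.GaitPlan(n_cycles=10, cycle_time_mean=1.1, cycle_time_cv=0.0,
                                stance_fraction=60.0)
        prox, dist = synthio.generate_quaternions(wf, plan, FS)
        track = kinematics.joint_angle(
            kinematics.sagittal_angle(dist), kinematics.sagittal_angle(prox), FS, "knee"
        )
        hs = synthio._heel_strike_samples(np.full(10, 1.1), FS, 0.5)
        mean = emg.mean_cycle(
            [emg.time_normalize(c) for c in emg.segment_cycles(track.angle_deg, hs)]
        ).values
        assert np.sqrt(np.mean((mean - wf.values) ** 2)) < 0.5
        assert abs(np.ptp(mean) - 53.7) < 0.5


class TestDetectEvents:
    @pytest.fixture(scope="class")
    def session(self):
        plan = synthio.GaitPlan(n_cycles=20, cycle_time_mean=1.1, cycle_time_cv=2.0,
                                stance_fraction=62.4)
        waveforms = {"knee": synthio.knee_like_waveform(50.0)}
        streams, truth = synthio.generate_imu_session(waveforms, plan, FS, seed=9)
        gyro = kinematics.angular_velocity_z(streams["shank"])
        return plan, truth, kinematics.detect_events(gyro, FS)

    def test_heel_strikes_within_20ms_of_truth(self, session):
        _, truth, events = session
        true_hs = truth["heel_strikes"][1:]
        m = min(events.heel_strikes.size, len(true_hs))
        err_ms = np.abs(events.heel_strikes[:m] - true_hs[:m]) / FS * 1e3
        assert np.max(err_ms) < 20.0

    def test_stance_fraction_recovered(self, session):
        plan, _, ev = session
        stance = np.mean(
            [
                (ev.toe_offs[k] - ev.heel_strikes[k])
                / (ev.heel_strikes[k + 1] - ev.heel_strikes[k])
                * 100.0
                for k in range(ev.toe_offs.size)
            ]
        )
        assert stance == pytest.approx(plan.stance_fraction, abs=1.0)

    def test_zero_cv_gives_equal_intervals(self):
        plan = synthio.GaitPlan(n_cycles=10, cycle_time_mean=1.1, cycle_time_cv=0.0,
                                stance_fraction=60.0)
        streams, _ = synthio.generate_imu_session({}, plan, FS, seed=1)
        ev = kinematics.detect_events(kinematics.angular_velocity_z(streams["shank"]), FS)
        assert np.ptp(np.diff(ev.heel_strikes)) <= 1

    def test_flat_signal_errors(self):
        with pytest.raises(ValueError):
            kinematics.detect_events(np.zeros(2000), FS)

    def test_event_alternation_enforced(self, session):
        _, _, ev = session
        for k in range(ev.toe_offs.size):
            assert ev.heel_strikes[k] < ev.toe_offs[k] < ev.heel_strikes[k + 1]


class TestTemporalParams:
    @staticmethod
    def events_from_intervals(intervals_s, stance=0.6, fs=100.0):
        hs = np.round(np.cumsum([0] + list(intervals_s)) * fs).astype(int)
        to = np.array(
            [hs[k] + int(stance * (hs[k + 1] - hs[k])) for k in range(hs.size - 1)]
        )
        return kinematics.GaitEvents(heel_strikes=hs, toe_offs=to), fs

    def test_velocity(self):
        ev, fs = self.events_from_intervals([1.0] * 3)
        out = kinematics.temporal_params(ev, fs, 30.0, 30.0)
        assert out.mean_velocity == pytest.approx(1.0)

    def test_zero_cv(self):
        ev, fs = self.events_from_intervals([1.0] * 3)
        out = kinematics.temporal_params(ev, fs, 30.0, 3.0)
        assert out.cycle_time_cv == pytest.approx(0.0)

    def test_cv_hand_computed(self):
        intervals = [1.0, 1.1, 0.9, 1.0]
        ev, fs = self.events_from_intervals(intervals)
        sample = kinematics.temporal_params(ev, fs, 30.0, 4.0, cv_ddof=1)
        population = kinematics.temporal_params(ev, fs, 30.0, 4.0, cv_ddof=0)
        assert sample.cycle_time_cv == pytest.approx(8.165, abs=0.01)
        assert population.cycle_time_cv == pytest.approx(7.071, abs=0.01)

    def test_rom_offset_invariant(self):
        ev, fs = self.events_from_intervals([1.0] * 3)
        curve = np.sin(np.linspace(0, 2 * np.pi, 101)) * 20.0
        a = kinematics.temporal_params(ev, fs, 30.0, 3.0, {"knee": curve})
        b = kinematics.temporal_params(ev, fs, 30.0, 3.0, {"knee": curve + 100.0})
        assert a.rom["knee"] == pytest.approx(b.rom["knee"])

    def test_zero_time_errors(self):
        ev, fs = self.events_from_intervals([1.0] * 3)
        with pytest.raises(ValueError):
            kinematics.temporal_params(ev, fs, 30.0, 0.0)
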