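"""Generator contracts: determinism, validation, ground-truth consistency."""

import numpy as np
import pytest

from gaitspm import emg, kinematics, spm, synthio


class TestProfilesAndPlans:
    def test_overlapping_bursts_rejected(self):
        with pytest.raises(ValueError):
            synthio.MuscleProfile("X", [(10, 50, 1.0), (40, 70, 1.0)], 0.0)

    def test_wrap_burst_accepted(self):
        p = synthio.MuscleProfile("X", [(90.0, 10.0, 1.0)], 0.0)
        assert p.unwrapped_bursts() == [(90.0, 110.0, 1.0)]

    def test_peak_below_floor_rejected(self):
        with pytest.raises(ValueError):
            synthio.MuscleProfile("X", [(10, 40, 0.05)], 0.1)

    def test_invalid_stance_rejected(self):
        with pytest.raises(ValueError):
            synthio.GaitPlan(stance_fraction=0.0)
        with pytest.raises(ValueError):
            synthio.GaitPlan(stance_fraction=100.0)


class TestEmgChannel:
    def test_no_bursts_zero_floor_is_silent(self, short_plan):
        prof = synthio.MuscleProfile("X", [], 0.0)
        channel, _ = synthio.generate_emg_channel(prof, short_plan, 1500.0, seed=1)
        assert np.all(channel == 0.0)

    def test_envelope_concentrated_in_bursts(self, single_burst_channel):
        channel, truth = single_burst_channel
        env = emg.envelope(emg.bandpass(channel, 1500.0), 1500.0).values
        mask = np.zeros(channel.size, dtype=bool)
        for on, off in truth["burst_windows"]:
            mask[on:off] = True
        assert env[mask].mean() > 5 * env[~mask].mean()

    def test_deterministic_under_seed(self, short_plan):
        prof = synthio.MuscleProfile("X", [(10, 40, 1.0)], 0.05)
        a, _ = synthio.generate_emg_channel(prof, short_plan, 1500.0, seed=7)
        b, _ = synthio.generate_emg_channel(prof, short_plan, 1500.0, seed=7)
        assert np.array_equal(a, b)

    def test_low_fs_rejected(self, short_plan):
        prof = synthio.MuscleProfile("X", [(10, 40, 1.0)], 0.05)
        with pytest.raises(ValueError):
            synthio.generate_emg_channel(prof, short_plan, 900.0, seed=1)


class TestFootswitch:
    def test_zero_cv_equal_cycles(self):
        plan = synthio.GaitPlan(n_cycles=10, cycle_time_mean=1.1, cycle_time_cv=0.0,
                                stance_fraction=60.0)
        _, hs = synthio.generate_footswitch(plan, 1500.0, seed=1)
        assert np.ptp(np.diff(hs)) <= 1

    def test_realized_cv_matches_plan(self):
        plan = synthio.GaitPlan(n_cycles=200, cycle_time_mean=1.1, cycle_time_cv=2.6,
                                stance_fraction=60.0)
        _, hs = synthio.generate_footswitch(plan, 1500.0, seed=1)
        ct = np.diff(hs) / 1500.0
        cv = np.std(ct, ddof=1) / ct.mean() * 100.0
        assert 2.1 <= cv <= 3.1

    def test_single_cycle_two_strikes(self):
        plan = synthio.GaitPlan(n_cycles=1, cycle_time_mean=1.0, cycle_time_cv=0.0,
                                stance_fraction=60.0)
        channel, hs = synthio.generate_footswitch(plan, 1500.0, seed=1)
        assert hs.size == 2
        rising = np.flatnonzero(np.diff(channel.astype(int)) == 1) + 1
        assert np.array_equal(rising, hs)

    def test_rising_edges_are_heel_strikes(self, short_plan):
        channel, hs = synthio.generate_footswitch(short_plan, 1500.0, seed=4)
        rising = np.flatnonzero(np.diff(channel.astype(int)) == 1) + 1
        assert np.array_equal(rising, hs)


class TestQuaternions:
    def test_zero_waveform_identity(self):
        wf = synthio.AngleWaveform("knee", np.zeros(101))
        plan = synthio.GaitPlan(n_cycles=3, cycle_time_mean=1.0, cycle_time_cv=0.0,
                                stance_fraction=60.0)
        prox, dist = synthio.generate_quaternions(wf, plan, 75.0)
        assert np.allclose(prox.quats[:, 0], 1.0)
        assert np.allclose(dist.quats[:, 0], 1.0)

    def test_negated_waveform_negates_angle(self):
        wf = synthio.knee_like_waveform(30.0)
        neg = synthio.AngleWaveform("knee", -wf.values)
        plan = synthio.GaitPlan(n_cycles=4, cycle_time_mean=1.0, cycle_time_cv=0.0,
                                stance_fraction=60.0)
        _, dist_pos = synthio.generate_quaternions(wf, plan, 75.0)
        _, dist_neg = synthio.generate_quaternions(neg, plan, 75.0)
        a = kinematics.sagittal_angle(dist_pos)
        b = kinematics.sagittal_angle(dist_neg)
        assert np.allclose(a, -b, atol=1e-9)

    def test_invalid_fs_rejected(self):
        wf = synthio.AngleWaveform("knee", np.zeros(101))
        with pytest.raises(ValueError):
            synthio.generate_quaternions(wf, synthio.GaitPlan(), 0.0)


class TestGroupDataset:
    @staticmethod
    def spec(plan=None):
        return {
            "profiles": [synthio.MuscleProfile("LG", [(10, 40, 1.0)], 0.05)],
            "waveforms": [synthio.knee_like_waveform(50.0)],
            "plan": plan or synthio.GaitPlan(),
        }

    def test_null_dataset_identical_specs_zero_sd(self):
        ds = synthio.generate_group_dataset(
            (self.spec(), self.spec()), (5, 5), between_subject_sd=0.0, seed=1
        )
        a = ds["A"]["emg"]["LG"]
        b = ds["B"]["emg"]["LG"]
        assert np.array_equal(a[0], a[1])
        res = spm.spm_ttest2(ds["A"]["angles"]["knee"], ds["B"]["angles"]["knee"])
        assert np.allclose(res.t_curve, 0.0)

    def test_between_subject_sd_realized(self):
        ds = synthio.generate_group_dataset(
            (self.spec(), self.spec()), (40, 40), between_subject_sd=0.3, seed=2
        )
        sd = ds["A"]["angles"]["knee"].std(axis=0, ddof=1).mean()
        assert sd == pytest.approx(0.3, rel=0.25)

    def test_deterministic_under_seed(self):
        d1 = synthio.generate_group_dataset(
            (self.spec(), self.spec()), (3, 3), 0.1, seed=5
        )
        d2 = synthio.generate_group_dataset(
            (self.spec(), self.spec()), (3, 3), 0.1, seed=5
        )
        assert np.array_equal(d1["A"]["emg"]["LG"], d2["A"]["emg"]["LG"])

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            synthio.generate_group_dataset(
                (self.spec(), self.spec()), (1, 5), 0.1, seed=1
            )

    def test_injected_band_difference_detected_reliably(self):
        """Two groups differing by +1 SD over 20-40 % of the cycle produce a
        supra-threshold cluster overlapping that band in most replicates
        (one-tailed, n = 13/14)."""
        base = synthio.knee_like_waveform(50.0)
        bump = np.zeros(101)
        bump[20:41] = 1.0
        shifted = synthio.AngleWaveform("knee", base.values + bump)
        det = 0
        reps = 40
        for seed in range(reps):
            ds = synthio.generate_group_dataset(
                (
                    {"waveforms": [base], "plan": synthio.GaitPlan()},
                    {"waveforms": [shifted], "plan": synthio.GaitPlan()},
                ),
                (13, 14),
                between_subject_sd=1.0,
                seed=seed,
            )
            res = spm.spm_ttest2(
                ds["A"]["angles"]["knee"], ds["B"]["angles"]["knee"], tails=1
            )
            det += any(c.start <= 40 and c.end >= 20 for c in res.clusters)
        assert det / reps >= 0.70  # consistent with the 0.80 design power


class TestImuSession:
    def test_calibration_window_is_still(self):
        plan = synthio.GaitPlan(n_cycles=5)
        streams, truth = synthio.generate_imu_session({}, plan, 75.0, seed=3)
        for stream in streams.values():
            ref = kinematics.calibrate_neutral(stream, 10.0)
            assert np.allclose(ref, [1, 0, 0, 0], atol=1e-9)

    def test_waveforms_recovered_through_joint_chain(self):
        plan = synthio.GaitPlan(n_cycles=12, cycle_time_cv=0.0)
        waveforms = {
            "hip": synthio.hip_like_waveform(35.4),
            "knee": synthio.knee_like_waveform(53.7),
            "ankle": synthio.ankle_like_waveform(27.3),
        }
        streams, truth = synthio.generate_imu_session(waveforms, plan, 75.0, seed=3)
        hs = truth["heel_strikes"]
        for joint, (p_site, d_site) in kinematics.JOINT_SEGMENTS.items():
            track = kinematics.joint_angle(
                kinematics.sagittal_angle(streams[d_site]),
                kinematics.sagittal_angle(streams[p_site]),
                75.0,
                joint,
            )
            cycles = [
                emg.time_normalize(c)
                for c in emg.segment_cycles(track.angle_deg, hs[2:-2])
            ]
            mean = emg.mean_cycle(cycles).values
            assert abs(np.ptp(mean) - np.ptp(waveforms[joint].values)) < 0.5
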