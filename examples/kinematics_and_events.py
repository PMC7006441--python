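"""Joint angles, gait events and temporal-spatial parameters from IMUs.

Generates a four-sensor quaternion session (pelvis, thigh, shank, foot)
whose hip/knee/ankle waveforms and stance fraction are known, then runs
the kinematic chain: neutral calibration, sagittal segment angles, joint
angles, shank-gyro event detection and temporal parameters. The printed
ROM, cycle time, CV and stance fraction should match the generator's
plan (ROM 35.4/53.7/27.3 deg, cycle 1.1 s, CV 2 %, stance 62.4 %).
"""

import numpy as np

from gaitspm import emg, kinematics, synthio

plan = synthio.GaitPlan(
    n_cycles=20, cycle_time_mean=1.1, cycle_time_cv=2.0, stance_fraction=62.4
)
waveforms = {
    "hip": synthio.hip_like_waveform(35.4),
    "knee": synthio.knee_like_waveform(53.7),
    "ankle": synthio.ankle_like_waveform(27.3),
}
streams, truth = synthio.generate_imu_session(waveforms, plan, fs=75.0, seed=11)

sagittal = {}
for site, stream in streams.items():
    reference = kinematics.calibrate_neutral(stream, window_s=10.0)
    relative = kinematics.relative_orientation(stream, reference)
    sagittal[site] = kinematics.sagittal_angle(relative)

events = kinematics.detect_events(
    kinematics.angular_velocity_z(streams["shank"]), fs=75.0
)
angle_cycles = {}
for joint, (proximal, distal) in kinematics.JOINT_SEGMENTS.items():
    track = kinematics.joint_angle(sagittal[distal], sagittal[proximal], 75.0, joint)
    cycles = [
        emg.time_normalize(c)
        for c in emg.segment_cycles(track.angle_deg, events.heel_strikes)
    ]
    angle_cycles[joint] = emg.mean_cycle(cycles).values

total_time = (events.heel_strikes[-1] - events.heel_strikes[0]) / 75.0
params = kinematics.temporal_params(
    events, 75.0, distance_m=30.0, total_time_s=total_time,
    mean_angle_cycles=angle_cycles,
)
print(f"{events.heel_strikes.size} heel strikes, {events.toe_offs.size} toe-offs")
print(f"cycle time {params.cycle_time:.3f} s, CV {params.cycle_time_cv:.2f} %")
print(f"stance {params.stance_pct:.1f} % of cycle")
for joint in ("hip", "knee", "ankle"):
    print(f"ROM {joint}: {params.rom[joint]:.1f} deg")
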