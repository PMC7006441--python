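"""Sagittal joint kinematics from IMU quaternions and temporal gait parameters.

Segment orientations arrive as unit-quaternion streams from four sensor
sites (pelvis, thigh, shank, foot). A 10 s quiet-standing window defines
the neutral reference per sensor; subsequent orientations are expressed
relative to it and decomposed with an intrinsic Z-Y-X Euler sequence where
z is the mediolateral axis, so the z component is the sagittal-plane
segment angle. A joint angle is the distal-minus-proximal segment angle
(sign convention per joint so flexion / dorsiflexion are positive),
low-passed at 10 Hz. Gait events are found on the shank angular velocity
about z: mid-swing produces a prominent positive peak, heel strike is the
first local minimum after it and toe-off the deepest local minimum before
it. Temporal-spatial parameters (mean velocity, cycle time and its CV,
stance fraction, ROM) follow from the events and the mean angle cycle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.spatial.transform import Rotation

#: sign applied to (distal - proximal) z-angle so flexion (hip, knee) and
#: dorsiflexion (ankle) are positive, extension / plantar flexion negative
JOINT_SIGNS = {"hip": 1.0, "knee": -1.0, "ankle": 1.0}

#: (proximal site, distal site) per joint
JOINT_SEGMENTS = {
    "hip": ("pelvis", "thigh"),
    "knee": ("thigh", "shank"),
    "ankle": ("shank", "foot"),
}


@dataclass
class QuaternionStream:
    """Unit quaternions (w, x, y, z) per sample from one sensor site."""

    quats: np.ndarray
    fs: float
    sensor_site: str = ""

    def __post_init__(self) -> None:
        self.quats = np.asarray(self.quats, dtype=float)
        if self.quats.ndim != 2 or self.quats.shape[1] != 4:
            raise ValueError("quats must have shape (n, 4) as (w, x, y, z)")
        norms = np.linalg.norm(self.quats, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("quaternions must be unit norm (|q| = 1 ± 1e-6)")

    def as_rotation(self) -> Rotation:
        # scipy stores quaternions as (x, y, z, w)
        return Rotation.from_quat(self.quats[:, [1, 2, 3, 0]])


@dataclass
class JointAngleTrack:
    """Calibrated flexion-extension angle time series for one joint."""

    joint: str
    angle_deg: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.angle_deg = np.asarray(self.angle_deg, dtype=float)
        if not np.all(np.isfinite(self.angle_deg)):
            raise ValueError("angles must be finite")


@dataclass
class GaitEvents:
    """Heel-strike and toe-off sample indices, strictly alternating."""

    heel_strikes: np.ndarray
    toe_offs: np.ndarray

    def __post_init__(self) -> None:
        self.heel_strikes = np.asarray(self.heel_strikes, dtype=int)
        self.toe_offs = np.asarray(self.toe_offs, dtype=int)
        hs, to = self.heel_strikes, self.toe_offs
        if np.any(np.diff(hs) <= 0) or np.any(np.diff(to) <= 0):
            raise ValueError("events must be strictly increasing")
        if to.size not in (hs.size - 1, hs.size):
            raise ValueError("expected one toe-off per delimited cycle")
        for k in range(min(to.size, hs.size - 1)):
            if not (hs[k] < to[k] < hs[k + 1]):
                raise ValueError("each toe-off must lie strictly between heel strikes")


@dataclass
class TemporalParams:
    mean_velocity: float  # m/s
    cycle_time: float  # s
    cycle_time_cv: float  # %
    stance_pct: float  # % of cycle
    rom: dict[str, float]  # degrees per joint


def _quat_mean(quats: np.ndarray) -> np.ndarray:
    """Mean orientation (Markley eigenvector method), w-positive."""
    q = np.asarray(quats, dtype=float)
    # hemisphere alignment to the first sample before averaging
    sign = np.where(q @ q[0] < 0, -1.0, 1.0)
    m = (q * sign[:, None]).T @ (q * sign[:, None])
    _, vecs = np.linalg.eigh(m)
    mean = vecs[:, -1]
    return mean if mean[0] >= 0 else -mean


def calibrate_neutral(
    stream: QuaternionStream, window_s: float = 10.0, motion_thresh_dps: float = 5.0
) -> np.ndarray:
    """Neutral-stance reference orientation from a quiet-standing window.

    The reference is the normalized quaternion mean over the window. A
    drift check rejects windows with real motion: the mean orientations of
    the two window halves must differ by less than ``motion_thresh_dps``
    per second of half-window (robust to sample-level sensor noise, which
    averages out).
    """
    n = int(round(window_s * stream.fs))
    if n < 2 or n > stream.quats.shape[0]:
        raise ValueError("calibration window outside the recording")
    q = stream.quats[:n]
    half = n // 2
    m1, m2 = _quat_mean(q[:half]), _quat_mean(q[half:])
    r_rel = Rotation.from_quat(m1[[1, 2, 3, 0]]).inv() * Rotation.from_quat(
        m2[[1, 2, 3, 0]]
    )
    drift_dps = np.degrees(np.linalg.norm(r_rel.as_rotvec())) / (half / stream.fs)
    if drift_dps > motion_thresh_dps:
        raise ValueError(
            f"motion during calibration window ({drift_dps:.1f} deg/s > "
            f"{motion_thresh_dps} deg/s): bad neutral calibration"
        )
    return _quat_mean(q)


def relative_orientation(
    stream: QuaternionStream, reference: np.ndarray
) -> QuaternionStream:
    """Express a stream relative to a reference orientation (axis reset)."""
    ref = Rotation.from_quat(np.asarray(reference)[[1, 2, 3, 0]])
    rel = ref.inv() * stream.as_rotation()
    q = rel.as_quat()[:, [3, 0, 1, 2]]
    return QuaternionStream(quats=q, fs=stream.fs, sensor_site=stream.sensor_site)


def to_euler(stream: QuaternionStream) -> np.ndarray:
    """Intrinsic Z-Y-X Euler angles in degrees, shape ``(n, 3)``.

    Column 0 is the rotation about the mediolateral z-axis, i.e. the
    sagittal-plane segment angle. Proximity to the gimbal singularity
    (|pitch| > 85 deg) triggers a warning.
    """
    angles = stream.as_rotation().as_euler("ZYX", degrees=True)
    if np.any(np.abs(angles[:, 1]) > 85.0):
        warnings.warn("pitch near gimbal singularity (|y| > 85 deg)")
    return angles


def sagittal_angle(stream: QuaternionStream) -> np.ndarray:
    """Sagittal (z-axis) segment angle in degrees."""
    return to_euler(stream)[:, 0]


def joint_angle(
    distal_z: np.ndarray,
    proximal_z: np.ndarray,
    fs: float,
    joint: str,
    cutoff_hz: float = 10.0,
    order: int = 4,
) -> JointAngleTrack:
    """Flexion-extension angle of the distal relative to the proximal segment.

    The difference of sagittal segment angles is sign-adjusted per joint
    (flexion / dorsiflexion positive) and low-passed with a zero-phase
    Butterworth filter at ``cutoff_hz``.
    """
    distal_z = np.asarray(distal_z, dtype=float)
    proximal_z = np.asarray(proximal_z, dtype=float)
    if distal_z.shape != proximal_z.shape:
        raise ValueError("distal and proximal angle series must have equal length")
    sign = JOINT_SIGNS.get(joint, 1.0)
    raw = sign * (distal_z - proximal_z)
    sos = signal.butter(order, cutoff_hz, btype="lowpass", fs=fs, output="sos")
    return JointAngleTrack(joint=joint, angle_deg=signal.sosfiltfilt(sos, raw), fs=fs)


def angular_velocity_z(stream: QuaternionStream) -> np.ndarray:
    """Angular velocity about the z-axis in deg/s, one value per sample."""
    rot = stream.as_rotation()
    rel = rot[:-1].inv() * rot[1:]
    omega = np.degrees(rel.as_rotvec()[:, 2]) * stream.fs
    return np.concatenate([omega, omega[-1:]])


def detect_events(
    shank_gyro_z: np.ndarray,
    fs: float,
    peak_prominence_dps: float = 50.0,
    min_peak_separation_s: float = 0.5,
) -> GaitEvents:
    """Heel strikes and toe-offs from the shank z angular velocity.

    Mid-swing shank rotation produces prominent, strongly positive peaks
    (the stance plateau between the heel-strike and toe-off dips is
    rejected by requiring peak height, not just prominence). Heel strike
    is the deepest local minimum in a window after each peak; toe-off is
    the deepest local minimum between the preceding heel strike and the
    peak. The default thresholds suit walking at 0.8-1.4 m/s.
    """
    g = np.asarray(shank_gyro_z, dtype=float)
    peaks, _ = signal.find_peaks(
        g,
        height=peak_prominence_dps,
        prominence=peak_prominence_dps,
        distance=max(1, int(round(min_peak_separation_s * fs))),
    )
    if peaks.size < 2:
        raise ValueError("fewer than two mid-swing peaks found; not enough gait cycles")
    minima, _ = signal.find_peaks(-g)
    window_n = max(1, int(round(min_peak_separation_s * fs)))
    heel_strikes = []
    for p in peaks:
        cand = minima[(minima > p) & (minima <= p + window_n)]
        if cand.size:
            heel_strikes.append(int(cand[np.argmin(g[cand])]))
    if len(heel_strikes) < 2:
        raise ValueError("could not locate heel strikes after mid-swing peaks")
    hs = np.array(heel_strikes)
    toe_offs = []
    for k in range(hs.size - 1):
        p = peaks[(peaks > hs[k]) & (peaks < hs[k + 1])]
        if p.size == 0:
            continue
        window = minima[(minima > hs[k]) & (minima < p[-1])]
        if window.size == 0:
            continue
        toe_offs.append(int(window[np.argmin(g[window])]))
    if len(toe_offs) != hs.size - 1:
        raise ValueError("could not locate a toe-off in every delimited cycle")
    return GaitEvents(heel_strikes=hs, toe_offs=np.array(toe_offs))


def temporal_params(
    events: GaitEvents,
    fs: float,
    distance_m: float,
    total_time_s: float,
    mean_angle_cycles: dict[str, np.ndarray] | None = None,
    cv_ddof: int = 1,
) -> TemporalParams:
    """Temporal-spatial gait parameters from events and mean angle cycles.

    Mean velocity is total distance over total time; cycle time statistics
    come from heel-strike intervals (CV as sample SD / mean by default);
    stance fraction is the toe-off position within each cycle; ROM per
    joint is max minus min of the mean normalized angle cycle.
    """
    if total_time_s <= 0:
        raise ValueError("total time must be positive")
    hs = events.heel_strikes
    if hs.size < 2:
        raise ValueError("need at least two heel strikes")
    cycle_times = np.diff(hs) / fs
    cv = float(np.std(cycle_times, ddof=cv_ddof) / np.mean(cycle_times) * 100.0)
    stance = [
        (events.toe_offs[k] - hs[k]) / (hs[k + 1] - hs[k]) * 100.0
        for k in range(min(events.toe_offs.size, hs.size - 1))
        if hs[k] < events.toe_offs[k] < hs[k + 1]
    ]
    rom = {}
    if mean_angle_cycles:
        rom = {
            joint: float(np.max(vals) - np.min(vals))
            for joint, vals in mean_angle_cycles.items()
        }
    return TemporalParams(
        mean_velocity=distance_m / total_time_s,
        cycle_time=float(np.mean(cycle_times)),
        cycle_time_cv=cv,
        stance_pct=float(np.mean(stance)) if stance else float("nan"),
        rom=rom,
    )
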