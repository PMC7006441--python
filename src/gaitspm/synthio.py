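"""Synthetic two-group gait sessions with known ground truth.

Every downstream stage (envelope extraction, burst detection, kinematics,
SPM) is testable against generated data whose burst timings, joint-angle
waveforms, cycle-time variability and stance fraction are known exactly.

EMG channels are built as burst-modulated band-limited Gaussian noise: a
20-450 Hz carrier (so the analysis band-pass is near-transparent)
multiplied by an amplitude template with raised-cosine ramps at burst
edges (default 20 ms), riding on a configurable noise floor. Heel-contact
timing comes from per-cycle durations drawn around the plan mean with the
requested coefficient of variation. IMU streams are pure z-axis (mediolateral)
rotations: the shank angle integrates a gait-like angular-velocity template
whose toe-off minimum sits at the plan's stance fraction, and the other
segments are chained off it so the hip/knee/ankle relative angles
reproduce the requested waveforms. Group datasets perturb per-subject
mean curves with smooth Gaussian fields (FWHM about 10 % of the cycle),
matching the smooth-field assumption of the random-field inference.

These are phenomenological signals: no motor-unit physiology, soft-tissue
artifact or sensor drift is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .emg import GRID_N, PCT_GRID
from .kinematics import JOINT_SIGNS, QuaternionStream

DEFAULT_RAMP_S = 0.020  #: raised-cosine burst edge duration, seconds
CALIBRATION_S = 10.0  #: neutral-standing lead-in for sensor calibration
SMOOTH_FWHM_NODES = 10.0  #: between-subject perturbation smoothness


@dataclass
class MuscleProfile:
    """Ground-truth burst plan for one muscle.

    Each burst is ``(onset_pct, offset_pct, peak_amp)``; a burst wrapping
    the cycle boundary is written with ``offset_pct < onset_pct`` and is
    unwrapped internally (offset + 100).
    """

    muscle_label: str
    bursts: list[tuple[float, float, float]] = field(default_factory=list)
    noise_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_floor < 0:
            raise ValueError("noise_floor must be >= 0")
        spans = []
        for onset, offset, peak in self.bursts:
            if not (0 <= onset <= 100):
                raise ValueError("burst onset must lie in [0, 100]")
            off = offset if offset > onset else offset + 100.0
            if not (onset < off <= onset + 100.0):
                raise ValueError("burst must have positive duration <= one cycle")
            if peak <= self.noise_floor:
                raise ValueError("peak_amp must exceed noise_floor")
            spans.append((onset, off))
        spans.sort()
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValueError("overlapping bursts within one muscle")
        if len(spans) >= 2 and spans[-1][1] - 100.0 > spans[0][0]:
            raise ValueError("overlapping bursts across the cycle boundary")

    def unwrapped_bursts(self) -> list[tuple[float, float, float]]:
        out = []
        for onset, offset, peak in self.bursts:
            off = offset if offset > onset else offset + 100.0
            out.append((onset, off, peak))
        return out


@dataclass
class GaitPlan:
    """Cycle-level plan: count, timing statistics, stance, distance."""

    n_cycles: int = 20
    cycle_time_mean: float = 1.1  # s
    cycle_time_cv: float = 1.7  # %
    stance_fraction: float = 57.3  # % of cycle
    walk_distance: float = 30.0  # m

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.cycle_time_mean <= 0:
            raise ValueError("cycle_time_mean must be positive")
        if not (0 < self.stance_fraction < 100):
            raise ValueError("stance_fraction must lie in (0, 100)")
        if self.cycle_time_cv < 0:
            raise ValueError("cycle_time_cv must be >= 0")


@dataclass
class AngleWaveform:
    """A joint flexion-extension waveform on the 0-100 % grid (degrees)."""

    joint: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (GRID_N,):
            raise ValueError(f"waveform must have {GRID_N} nodes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("waveform must be finite")


def realized_cycle_times(plan: GaitPlan, rng: np.random.Generator) -> np.ndarray:
    """Per-cycle durations (s) around the plan mean with the plan CV."""
    sd = plan.cycle_time_cv / 100.0 * plan.cycle_time_mean
    times = rng.normal(plan.cycle_time_mean, sd, size=plan.n_cycles)
    return np.clip(times, 0.3 * plan.cycle_time_mean, None)


def _heel_strike_samples(
    cycle_times: np.ndarray, fs: float, lead_in_s: float
) -> np.ndarray:
    edges = lead_in_s + np.concatenate([[0.0], np.cumsum(cycle_times)])
    return np.round(edges * fs).astype(int)


def _raised_cosine_template(
    n_samples: int,
    hs: np.ndarray,
    bursts: list[tuple[float, float, float]],
    noise_floor: float,
    fs: float,
    ramp_s: float,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Amplitude template over the whole recording plus truth windows."""
    template = np.full(n_samples, noise_floor)
    truth: list[tuple[int, int]] = []
    ramp_n = max(1, int(round(ramp_s * fs)))
    ramp_up = 0.5 * (1 - np.cos(np.linspace(0, np.pi, ramp_n)))
    for k in range(hs.size - 1):
        span = hs[k + 1] - hs[k]
        for onset_pct, offset_u, peak in bursts:
            on = hs[k] + int(round(onset_pct / 100.0 * span))
            off = hs[k] + int(round(offset_u / 100.0 * span))
            on_r = min(on + ramp_n, off)
            off_r = max(off - ramp_n, on_r)
            seg = slice(max(on, 0), min(off, n_samples))
            if seg.start >= seg.stop:
                continue
            shape = np.full(off - on, peak)
            shape[: on_r - on] = noise_floor + (peak - noise_floor) * ramp_up[: on_r - on]
            if off > off_r:
                shape[-(off - off_r) :] = noise_floor + (peak - noise_floor) * ramp_up[
                    : off - off_r
                ][::-1]
            template[seg] = np.maximum(template[seg], shape[: seg.stop - seg.start])
            truth.append((max(on, 0), min(off, n_samples)))
    return template, truth


def _band_limited_noise(
    n: int, fs: float, rng: np.random.Generator, low_hz: float = 20.0, high_hz: float = 450.0
) -> np.ndarray:
    white = rng.standard_normal(n)
    sos = signal.butter(4, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    carrier = signal.sosfiltfilt(sos, white)
    return carrier / carrier.std()


def generate_emg_channel(
    profile: MuscleProfile,
    plan: GaitPlan,
    fs: float,
    seed: int,
    ramp_s: float = DEFAULT_RAMP_S,
    cycle_times: np.ndarray | None = None,
    lead_in_s: float = 0.5,
) -> tuple[np.ndarray, dict]:
    """One raw EMG channel plus ground truth.

    Returns the channel and a dict with ``heel_strikes`` (sample indices)
    and ``burst_windows`` (absolute sample intervals per realized burst).
    The channel is zero-mean broadband noise whose amplitude envelope
    follows the profile's burst plan.
    """
    if fs <= 1000:
        raise ValueError("fs must exceed 1000 Hz for a 20-500 Hz analysis band")
    rng = np.random.default_rng(seed)
    if cycle_times is None:
        cycle_times = realized_cycle_times(plan, rng)
    hs = _heel_strike_samples(cycle_times, fs, lead_in_s)
    n = hs[-1] + int(round(lead_in_s * fs))
    template, truth = _raised_cosine_template(
        n, hs, profile.unwrapped_bursts(), profile.noise_floor, fs, ramp_s
    )
    if np.all(template == 0):
        channel = np.zeros(n)
    else:
        channel = template * _band_limited_noise(n, fs, rng)
    return channel, {"heel_strikes": hs, "burst_windows": truth}


def generate_footswitch(
    plan: GaitPlan,
    fs: float,
    seed: int,
    cycle_times: np.ndarray | None = None,
    lead_in_s: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary heel-contact channel and heel-strike sample indices.

    The switch is high from each heel strike until the plan's stance
    fraction of that cycle; rising edges are exactly the heel strikes.
    """
    rng = np.random.default_rng(seed)
    if cycle_times is None:
        cycle_times = realized_cycle_times(plan, rng)
    hs = _heel_strike_samples(cycle_times, fs, lead_in_s)
    n = hs[-1] + int(round(lead_in_s * fs))
    channel = np.zeros(n, dtype=np.uint8)
    for k in range(hs.size - 1):
        off = hs[k] + int(round(plan.stance_fraction / 100.0 * (hs[k + 1] - hs[k])))
        channel[hs[k] : off] = 1
    # partial stance after the final heel strike so its rising edge exists
    tail = hs[-1] + int(
        round(plan.stance_fraction / 100.0 * plan.cycle_time_mean * fs)
    )
    channel[hs[-1] : min(tail, n)] = 1
    return channel, hs


def _angle_track(
    waveform_values: np.ndarray, hs: np.ndarray, n_samples: int, endpoint: bool = True
) -> np.ndarray:
    """Evaluate a 0-100 % waveform over realized cycles in absolute samples.

    With ``endpoint=True`` node 100 lands on the cycle's last sample,
    matching how cycles are read back (cycle k = [HS_k, HS_{k+1}),
    endpoints mapped to nodes 0/100); with ``endpoint=False`` the cycle
    occupies exactly [0, 100) so absolute template positions (e.g. the
    toe-off dip of the angular-velocity template) fall at their exact
    fraction of the realized cycle.
    """
    track = np.full(n_samples, waveform_values[0], dtype=float)
    for k in range(hs.size - 1):
        span = hs[k + 1] - hs[k]
        denom = max(span - 1, 1) if endpoint else span
        pct = np.arange(span) / denom * 100.0
        stop = min(hs[k + 1], n_samples)
        if hs[k] >= n_samples:
            break
        track[hs[k] : stop] = np.interp(pct, PCT_GRID, waveform_values)[: stop - hs[k]]
    track[hs[-1] :] = waveform_values[0]
    return track


def _zrot_stream(z_deg: np.ndarray, fs: float, site: str = "") -> QuaternionStream:
    half = np.radians(z_deg) / 2.0
    quats = np.column_stack(
        [np.cos(half), np.zeros_like(half), np.zeros_like(half), np.sin(half)]
    )
    return QuaternionStream(quats=quats, fs=fs, sensor_site=site)


def generate_quaternions(
    waveform: AngleWaveform,
    plan: GaitPlan,
    fs: float,
    cycle_times: np.ndarray | None = None,
    lead_in_s: float = 0.5,
) -> tuple[QuaternionStream, QuaternionStream]:
    """Proximal and distal quaternion streams encoding one joint waveform.

    The proximal stream is the identity; the distal stream rotates about
    the mediolateral z-axis so that the distal-minus-proximal sagittal
    angle (with the joint's sign convention) reproduces the waveform each
    cycle.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if cycle_times is None:
        cycle_times = np.full(plan.n_cycles, plan.cycle_time_mean)
    hs = _heel_strike_samples(cycle_times, fs, lead_in_s)
    n = hs[-1] + int(round(lead_in_s * fs))
    sign = JOINT_SIGNS.get(waveform.joint, 1.0)
    track = _angle_track(sign * waveform.values, hs, n)
    proximal = _zrot_stream(np.zeros(n), fs, "proximal")
    distal = _zrot_stream(track, fs, "distal")
    return proximal, distal


def shank_gyro_template(plan: GaitPlan) -> np.ndarray:
    """Per-cycle shank angular-velocity template (deg/s on the % grid).

    Mid-swing carries a prominent positive peak, heel strike (0/100 %)
    and toe-off (at the plan's stance fraction) carry negative minima, so
    event detection can be validated against known event positions. The
    template integrates to zero over the cycle (the shank returns to the
    same orientation each stride).
    """
    sf = plan.stance_fraction
    mid_swing = (sf + 100.0) / 2.0
    g = lambda c, w: np.exp(-0.5 * ((PCT_GRID - c) / w) ** 2)
    # heel-strike dip sits at node 0 only, so its minimum falls exactly on
    # the cycle-boundary sample of the realized track
    tpl = 300.0 * g(mid_swing, 4.0) - 150.0 * g(sf, 2.0) - 120.0 * g(0.0, 1.5)
    return tpl - tpl.mean()


def generate_imu_session(
    waveforms: dict[str, AngleWaveform],
    plan: GaitPlan,
    fs: float,
    seed: int,
    cycle_times: np.ndarray | None = None,
    angle_noise_deg: float = 0.0,
    calibration_s: float = CALIBRATION_S,
) -> tuple[dict[str, QuaternionStream], dict]:
    """Four-site quaternion streams (pelvis/thigh/shank/foot) plus truth.

    The shank sagittal angle is the integral of the gait angular-velocity
    template; the thigh, pelvis and foot angles are chained off it so the
    hip/knee/ankle distal-minus-proximal angles reproduce ``waveforms``.
    A ``calibration_s`` neutral-standing lead-in precedes gait. Truth
    holds heel-strike and toe-off sample indices and the realized cycle
    times.
    """
    rng = np.random.default_rng(seed)
    if cycle_times is None:
        cycle_times = realized_cycle_times(plan, rng)
    hs = _heel_strike_samples(cycle_times, fs, lead_in_s=calibration_s)
    n = hs[-1] + int(round(1.0 * fs))
    # a phantom extra cycle supplies the heel-strike dip at the final
    # boundary; the track is silenced shortly after it
    hs_ext = np.append(hs, hs[-1] + int(round(plan.cycle_time_mean * fs)))
    gyro_track = _angle_track(shank_gyro_template(plan), hs_ext, n, endpoint=False)
    gyro_track[: hs[0]] = 0.0
    gyro_track[min(hs[-1] + int(round(0.1 * fs)), n) :] = 0.0
    shank_z = np.cumsum(gyro_track) / fs

    def wf(joint: str) -> np.ndarray:
        w = waveforms.get(joint)
        return w.values if w is not None else np.zeros(GRID_N)

    knee = _angle_track(wf("knee"), hs, n)
    hip = _angle_track(wf("hip"), hs, n)
    ankle = _angle_track(wf("ankle"), hs, n)
    for track in (knee, hip, ankle):
        track[: hs[0]] = 0.0
        track[hs[-1] :] = 0.0
    thigh_z = shank_z - JOINT_SIGNS["knee"] * knee
    pelvis_z = thigh_z - JOINT_SIGNS["hip"] * hip
    foot_z = shank_z + JOINT_SIGNS["ankle"] * ankle
    z_tracks = {"pelvis": pelvis_z, "thigh": thigh_z, "shank": shank_z, "foot": foot_z}
    streams = {}
    for site, z in z_tracks.items():
        noisy = z + angle_noise_deg * rng.standard_normal(n) if angle_noise_deg else z
        streams[site] = _zrot_stream(noisy, fs, site)
    to = np.array(
        [
            hs[k] + int(round(plan.stance_fraction / 100.0 * (hs[k + 1] - hs[k])))
            for k in range(hs.size - 1)
        ]
    )
    truth = {
        "heel_strikes": hs,
        "toe_offs": to,
        "cycle_times": cycle_times,
        "calibration_samples": hs[0],
    }
    return streams, truth


def smooth_field(
    n_nodes: int, rng: np.random.Generator, fwhm_nodes: float = SMOOTH_FWHM_NODES
) -> np.ndarray:
    """Unit-variance smooth Gaussian field on a 1D grid (given FWHM)."""
    sigma = fwhm_nodes / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    pad = int(np.ceil(4 * sigma))
    white = rng.standard_normal(n_nodes + 2 * pad)
    x = np.arange(-pad, pad + 1)
    kernel = np.exp(-0.5 * (x / sigma) ** 2)
    smoothed = np.convolve(white, kernel, mode="same")[pad:-pad]
    return smoothed / np.sqrt(np.sum(kernel**2))


def envelope_template_curve(
    profile: MuscleProfile, plan: GaitPlan, ramp_s: float = DEFAULT_RAMP_S
) -> np.ndarray:
    """Expected envelope of a profile on the 0-100 % grid (template units)."""
    ramp_pct = ramp_s / plan.cycle_time_mean * 100.0
    curve = np.full(GRID_N, profile.noise_floor)
    for onset, off_u, peak in profile.unwrapped_bursts():
        for base in (0.0, -100.0):  # wrap contribution into [0, 100]
            on, off = onset + base, off_u + base
            rise = np.clip((PCT_GRID - on) / ramp_pct, 0.0, 1.0)
            fall = np.clip((off - PCT_GRID) / ramp_pct, 0.0, 1.0)
            shape = np.where(
                (PCT_GRID >= on) & (PCT_GRID <= off),
                profile.noise_floor
                + (peak - profile.noise_floor)
                * 0.5
                * (1 - np.cos(np.pi * np.minimum(rise, fall))),
                profile.noise_floor,
            )
            curve = np.maximum(curve, shape)
    return curve


def generate_group_dataset(
    group_specs: tuple[dict, dict],
    n_subjects: tuple[int, int],
    between_subject_sd: float,
    seed: int,
    fwhm_nodes: float = SMOOTH_FWHM_NODES,
) -> dict:
    """Per-subject mean-cycle dataset for two groups.

    Each spec is ``{"profiles": [MuscleProfile, ...], "waveforms":
    [AngleWaveform, ...], "plan": GaitPlan}``. Every subject's mean curve
    is the group template plus a smooth unit-variance Gaussian field
    scaled by ``between_subject_sd`` (EMG curves are clipped at zero).
    Identical specs with zero SD give a null dataset.
    """
    if any(n < 2 for n in n_subjects):
        raise ValueError("need at least 2 subjects per group")
    rng = np.random.default_rng(seed)
    out: dict = {}
    for gname, spec, n_subj in zip(("A", "B"), group_specs, n_subjects):
        plan = spec["plan"]
        emg_templates = {
            p.muscle_label: envelope_template_curve(p, plan)
            for p in spec.get("profiles", [])
        }
        angle_templates = {w.joint: w.values for w in spec.get("waveforms", [])}
        emg = {
            m: np.vstack(
                [
                    np.clip(
                        tpl + between_subject_sd * smooth_field(GRID_N, rng, fwhm_nodes),
                        0.0,
                        None,
                    )
                    for _ in range(n_subj)
                ]
            )
            for m, tpl in emg_templates.items()
        }
        angles = {
            j: np.vstack(
                [
                    tpl + between_subject_sd * smooth_field(GRID_N, rng, fwhm_nodes)
                    for _ in range(n_subj)
                ]
            )
            for j, tpl in angle_templates.items()
        }
        out[gname] = {"emg": emg, "angles": angles, "plan": plan}
    return out


def knee_like_waveform(rom_deg: float = 53.7) -> AngleWaveform:
    """A smooth knee-like flexion waveform with the requested ROM.

    Small flexion wave in stance, large flexion peak in swing - the shape
    of a healthy knee sagittal trace, scaled to ``rom_deg``.
    """
    pct = PCT_GRID
    shape = 0.18 * np.exp(-0.5 * ((pct - 15) / 8.0) ** 2) + 1.0 * np.exp(
        -0.5 * ((pct - 72) / 9.0) ** 2
    )
    shape = shape - shape.min()
    values = shape / np.ptp(shape) * rom_deg
    values[-1] = values[0]  # periodic continuity at the heel strike
    return AngleWaveform(joint="knee", values=values)


def hip_like_waveform(rom_deg: float = 35.4) -> AngleWaveform:
    """Hip flexion-extension: flexed at contact, extended in late stance."""
    pct = PCT_GRID
    shape = np.cos(2 * np.pi * (pct - 5.0) / 100.0)
    values = (shape - shape.min()) / np.ptp(shape) * rom_deg
    values[-1] = values[0]
    return AngleWaveform(joint="hip", values=values)


def ankle_like_waveform(rom_deg: float = 27.3) -> AngleWaveform:
    """Ankle dorsi/plantar flexion with push-off plantar-flexion trough."""
    pct = PCT_GRID
    shape = 0.45 * np.exp(-0.5 * ((pct - 40) / 12.0) ** 2) - 1.0 * np.exp(
        -0.5 * ((pct - 63) / 6.0) ** 2
    )
    values = (shape - shape.min()) / np.ptp(shape) * rom_deg
    values[-1] = values[0]
    return AngleWaveform(joint="ankle", values=values)
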