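"""End-to-end orchestration: session files, configuration, subject and
group-level analysis.

A session on disk is a pair of plain-text files per subject: an EMG CSV
(``time_s`` plus one column per muscle plus ``footswitch``) and a
quaternion CSV (``time_s`` plus ``<site>_w/x/y/z`` for the four sensor
sites), each with a JSON sidecar carrying the sampling rate and channel
mapping. ``run_subject`` turns a session into a results bundle of
mean-cycle representations (EMG envelopes, co-contraction curves, burst
timings, joint-angle cycles, temporal-spatial parameters);
``run_group_comparison`` turns two lists of bundles into a report of SPM
waveform comparisons and scalar tests.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bursts as bursts_mod
from . import coactivation, emg, kinematics, spm, synthio

MUSCLES = ["MG", "LG", "SOL", "TA", "VL", "VM", "RF", "ST", "BF", "GMAX", "GMED"]
SITES = ["pelvis", "thigh", "shank", "foot"]


@dataclass
class AnalysisConfig:
    """All tunable analysis constants, defaulting to the standard protocol."""

    bandpass_low_hz: float = 20.0
    bandpass_high_hz: float = 500.0
    bandpass_order: int = 5
    envelope_cutoff_hz: float = 6.0
    angle_cutoff_hz: float = 10.0
    min_burst_ms: float = 5.0
    merge_gap_ms: float = 125.0
    kmeans_clusters: int = 3
    burst_input: str = "rectified"  # or "envelope"
    rf_second_burst_window: tuple[float, float] = (45.0, 75.0)
    n_cycles: int = 20
    normalization_mode: str = "max"  # or "median"
    alpha: float = 0.05
    event_prominence_dps: float = 50.0
    event_min_separation_s: float = 0.5
    cv_ddof: int = 1
    calibration_window_s: float = 10.0
    distance_m: float = 30.0
    seed: int = 0

    def save(self, path: str | Path) -> None:
        d = asdict(self)
        d["rf_second_burst_window"] = list(d["rf_second_burst_window"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "AnalysisConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["rf_second_burst_window"] = tuple(d["rf_second_burst_window"])
        return cls(**d)


@dataclass
class SessionManifest:
    """Pointers to one subject's session files."""

    subject_id: str
    group: str  # control | patient
    condition: str  # preferred | slow
    emg_csv: str
    quat_csv: str
    distance_m: float = 30.0

    def __post_init__(self) -> None:
        if self.group not in ("control", "patient"):
            raise ValueError("group must be 'control' or 'patient'")
        if self.condition not in ("preferred", "slow"):
            raise ValueError("condition must be 'preferred' or 'slow'")


# ---------------------------------------------------------------- session I/O


def write_emg_csv(
    path: str | Path, session: emg.EmgSession
) -> None:
    path = Path(path)
    n = session.channels.shape[1]
    data = {"time_s": np.arange(n) / session.fs}
    for lab, ch in zip(session.muscle_labels, session.channels):
        data[lab] = ch
    if session.footswitch is not None:
        data["footswitch"] = session.footswitch
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6g")
    sidecar = {"fs": session.fs, "muscle_labels": session.muscle_labels}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_emg_session(path: str | Path) -> emg.EmgSession:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    df = pd.read_csv(path)
    channels = np.vstack([df[lab].to_numpy() for lab in meta["muscle_labels"]])
    fsw = df["footswitch"].to_numpy() if "footswitch" in df else None
    return emg.EmgSession(
        channels=channels,
        fs=meta["fs"],
        muscle_labels=list(meta["muscle_labels"]),
        footswitch=fsw,
    )


def write_quat_csv(
    path: str | Path, streams: dict[str, kinematics.QuaternionStream]
) -> None:
    path = Path(path)
    fs = next(iter(streams.values())).fs
    n = next(iter(streams.values())).quats.shape[0]
    data = {"time_s": np.arange(n) / fs}
    for site, stream in streams.items():
        for j, comp in enumerate("wxyz"):
            data[f"{site}_{comp}"] = stream.quats[:, j]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")
    sidecar = {"fs": fs, "sites": list(streams)}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_quat_session(path: str | Path) -> dict[str, kinematics.QuaternionStream]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    df = pd.read_csv(path)
    streams = {}
    for site in meta["sites"]:
        q = np.column_stack([df[f"{site}_{c}"].to_numpy() for c in "wxyz"])
        q /= np.linalg.norm(q, axis=1, keepdims=True)  # undo CSV rounding
        streams[site] = kinematics.QuaternionStream(
            quats=q, fs=meta["fs"], sensor_site=site
        )
    return streams


# ----------------------------------------------------- synthetic session setup


def default_profiles(group: str = "control") -> list[synthio.MuscleProfile]:
    """Canonical burst plans per muscle for a synthetic gait session.

    Timings follow textbook adult gait. The patient variant shifts the
    gastrocnemii to an earlier onset and prolongs knee flexor/extensor
    activity into mid stance - the qualitative signature of arthropathic
    gait - so group comparisons on synthetic data have real structure.
    """
    control = {
        "MG": [(15.0, 50.0, 1.0)],
        "LG": [(15.0, 50.0, 1.0)],
        "SOL": [(8.0, 50.0, 1.0)],
        "TA": [(55.0, 10.0, 1.0)],
        "VL": [(88.0, 15.0, 1.0)],
        "VM": [(88.0, 15.0, 1.0)],
        "RF": [(92.0, 12.0, 1.0), (50.0, 65.0, 0.6)],
        "ST": [(80.0, 5.0, 1.0)],
        "BF": [(80.0, 5.0, 1.0)],
        "GMAX": [(90.0, 20.0, 1.0)],
        "GMED": [(95.0, 25.0, 1.0)],
    }
    patient = dict(control)
    patient["MG"] = [(8.0, 50.0, 1.0)]
    patient["LG"] = [(6.0, 50.0, 1.0)]
    patient["VL"] = [(88.0, 28.0, 1.0)]
    patient["VM"] = [(88.0, 28.0, 1.0)]
    patient["ST"] = [(80.0, 18.0, 1.0)]
    patient["BF"] = [(80.0, 18.0, 1.0)]
    patient["GMAX"] = [(90.0, 30.0, 1.0)]
    table = patient if group == "patient" else control
    return [
        synthio.MuscleProfile(muscle_label=m, bursts=table[m], noise_floor=0.05)
        for m in MUSCLES
    ]


def default_waveforms(group: str = "control") -> dict[str, synthio.AngleWaveform]:
    """Joint waveforms with group-typical ROM (reduced in the patient group)."""
    if group == "patient":
        roms = {"hip": 29.8, "knee": 39.3, "ankle": 19.8}
    else:
        roms = {"hip": 35.4, "knee": 53.7, "ankle": 27.3}
    return {
        "hip": synthio.hip_like_waveform(roms["hip"]),
        "knee": synthio.knee_like_waveform(roms["knee"]),
        "ankle": synthio.ankle_like_waveform(roms["ankle"]),
    }


def default_plan(group: str = "control", n_cycles: int = 22) -> synthio.GaitPlan:
    if group == "patient":
        return synthio.GaitPlan(
            n_cycles=n_cycles,
            cycle_time_mean=1.1,
            cycle_time_cv=2.6,
            stance_fraction=62.4,
        )
    return synthio.GaitPlan(
        n_cycles=n_cycles, cycle_time_mean=1.1, cycle_time_cv=1.7, stance_fraction=57.3
    )


#: between-subject SDs used when sampling per-subject gait conditions;
#: scaled to the spread typical of small adult cohorts
SUBJECT_SD = {
    "cycle_time_s": 0.1,
    "cycle_time_cv_pct": {"control": 0.5, "patient": 0.7},
    "stance_pct": {"control": 3.0, "patient": 3.8},
    "rom_deg": {"hip": 5.0, "knee": 7.0, "ankle": 5.7},
    "burst_timing_pct": 2.0,
}


def sample_subject_conditions(
    group: str, rng: np.random.Generator, n_cycles: int = 22
) -> tuple[synthio.GaitPlan, list[synthio.MuscleProfile], dict[str, synthio.AngleWaveform]]:
    """Draw one subject's gait conditions around the group templates.

    Cycle timing, stance fraction, joint ROMs and burst on/offsets are
    jittered with the between-subject SDs above so simulated cohorts have
    realistic subject-to-subject spread rather than identical waveforms.
    """
    base_plan = default_plan(group, n_cycles)
    cv_sd = SUBJECT_SD["cycle_time_cv_pct"][group if group in ("control", "patient") else "control"]
    st_sd = SUBJECT_SD["stance_pct"][group if group in ("control", "patient") else "control"]
    plan = synthio.GaitPlan(
        n_cycles=n_cycles,
        cycle_time_mean=max(0.6, rng.normal(base_plan.cycle_time_mean, SUBJECT_SD["cycle_time_s"])),
        cycle_time_cv=max(0.3, rng.normal(base_plan.cycle_time_cv, cv_sd)),
        stance_fraction=float(np.clip(rng.normal(base_plan.stance_fraction, st_sd), 45.0, 75.0)),
    )
    profiles = []
    for prof in default_profiles(group):
        bursts_j = []
        for onset, offset, peak in prof.bursts:
            shift = rng.normal(0.0, SUBJECT_SD["burst_timing_pct"])
            stretch = rng.normal(0.0, SUBJECT_SD["burst_timing_pct"])
            bursts_j.append(
                (
                    (onset + shift) % 100.0,
                    (offset + shift + stretch) % 100.0,
                    peak * float(np.clip(rng.normal(1.0, 0.1), 0.5, 1.5)),
                )
            )
        try:
            profiles.append(
                synthio.MuscleProfile(prof.muscle_label, bursts_j, prof.noise_floor)
            )
        except ValueError:
            profiles.append(prof)  # jitter produced an invalid plan: keep template
    base_wf = default_waveforms(group)
    waveforms = {}
    for joint, wf in base_wf.items():
        rom = np.ptp(wf.values)
        new_rom = max(5.0, rng.normal(rom, SUBJECT_SD["rom_deg"][joint]))
        shape = wf.values * (new_rom / rom) + 1.5 * synthio.smooth_field(101, rng)
        shape[-1] = shape[0]
        waveforms[joint] = synthio.AngleWaveform(joint, shape)
    return plan, profiles, waveforms


def simulate_session(
    out_dir: str | Path,
    seed: int,
    group: str = "control",
    condition: str = "preferred",
    subject_id: str = "S00",
    fs_emg: float = 1500.0,
    fs_imu: float = 75.0,
    n_cycles: int = 22,
    subject_variability: bool = True,
) -> SessionManifest:
    """Generate and write one synthetic subject session (CSV + sidecars).

    EMG, footswitch and IMU streams share one realization of the cycle
    times so heel strikes agree across modalities; ground truth (realized
    per-subject plan, burst profiles and joint ROMs) goes to
    ``truth.json`` next to the data. With ``subject_variability`` the
    subject's conditions are drawn around the group templates; without
    it the templates are used verbatim.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    if subject_variability:
        plan, profiles, waveforms = sample_subject_conditions(group, rng, n_cycles)
    else:
        plan = default_plan(group, n_cycles)
        profiles = default_profiles(group)
        waveforms = default_waveforms(group)
    cycle_times = synthio.realized_cycle_times(plan, rng)
    channels, truths = [], {}
    for i, prof in enumerate(profiles):
        ch, truth = synthio.generate_emg_channel(
            prof, plan, fs_emg, seed=seed + 1 + i, cycle_times=cycle_times
        )
        channels.append(ch)
        truths[prof.muscle_label] = truth
    fsw, hs = synthio.generate_footswitch(
        plan, fs_emg, seed=seed, cycle_times=cycle_times
    )
    n = min(min(c.size for c in channels), fsw.size)
    session = emg.EmgSession(
        channels=np.vstack([c[:n] for c in channels]),
        fs=fs_emg,
        muscle_labels=MUSCLES,
        footswitch=fsw[:n],
    )
    emg_csv = out / f"{subject_id}_emg.csv"
    write_emg_csv(emg_csv, session)

    streams, imu_truth = synthio.generate_imu_session(
        waveforms, plan, fs_imu, seed=seed, cycle_times=cycle_times
    )
    quat_csv = out / f"{subject_id}_imu.csv"
    write_quat_csv(quat_csv, streams)

    truth = {
        "plan": asdict(plan),
        "heel_strikes_emg": hs.tolist(),
        "heel_strikes_imu": imu_truth["heel_strikes"].tolist(),
        "toe_offs_imu": imu_truth["toe_offs"].tolist(),
        "cycle_times": np.asarray(cycle_times).tolist(),
        "burst_profiles": {
            p.muscle_label: {"bursts": p.bursts, "noise_floor": p.noise_floor}
            for p in profiles
        },
        "rom": {j: float(np.ptp(w.values)) for j, w in waveforms.items()},
    }
    (out / f"{subject_id}_truth.json").write_text(json.dumps(truth, indent=1))
    manifest = SessionManifest(
        subject_id=subject_id,
        group=group,
        condition=condition,
        emg_csv=str(emg_csv),
        quat_csv=str(quat_csv),
    )
    (out / f"{subject_id}_manifest.json").write_text(
        json.dumps(asdict(manifest), indent=1)
    )
    return manifest


# ------------------------------------------------------------- subject level


def _footswitch_heel_strikes(footswitch: np.ndarray) -> np.ndarray:
    fsw = np.asarray(footswitch) > 0.5
    edges = np.flatnonzero(np.diff(fsw.astype(int)) == 1) + 1
    if fsw[0]:
        edges = np.concatenate([[0], edges])
    return edges


def run_subject(manifest: SessionManifest, config: AnalysisConfig | None = None) -> dict:
    """Full per-subject analysis: one session in, one results bundle out."""
    cfg = config or AnalysisConfig()
    session = read_emg_session(manifest.emg_csv)
    if session.footswitch is None:
        raise ValueError("session has no footswitch channel; cannot segment cycles")
    missing = [m for m in MUSCLES if m not in session.muscle_labels]
    if missing:
        raise ValueError(f"missing muscle channels: {missing}")
    hs = _footswitch_heel_strikes(session.footswitch)
    n_avail = hs.size - 1
    n_use = min(n_avail, cfg.n_cycles)
    if n_avail < cfg.n_cycles:
        warnings.warn(
            f"only {n_avail} cycles available, config requests {cfg.n_cycles}"
        )
    hs_used = hs[: n_use + 1]

    emg_mean: dict[str, np.ndarray] = {}
    norm_cycles: dict[str, list[emg.NormalizedCycleSeries]] = {}
    burst_timing: dict[str, dict] = {}
    for label in session.muscle_labels:
        filt = emg.bandpass(
            session.channel(label),
            session.fs,
            cfg.bandpass_low_hz,
            cfg.bandpass_high_hz,
            cfg.bandpass_order,
        )
        env = emg.envelope(filt, session.fs, cfg.envelope_cutoff_hz)
        cycles = [
            emg.time_normalize(c) for c in emg.segment_cycles(env.values, hs_used)
        ]
        cycles, _ = emg.amplitude_normalize(cycles, mode=cfg.normalization_mode)
        norm_cycles[label] = cycles
        emg_mean[label] = emg.mean_cycle(cycles).values

        rect = emg.rectify(filt) if cfg.burst_input == "rectified" else env.values
        train = bursts_mod.detect_activity(rect, session.fs, muscle_label=label)
        train = bursts_mod.clean(train, cfg.min_burst_ms, cfg.merge_gap_ms)
        window = cfg.rf_second_burst_window if label == "RF" else None
        try:
            timing = bursts_mod.cycle_timing(train, hs_used, window)
            burst_timing[label] = {
                "onset_pct": timing.onset_pct,
                "offset_pct": timing.offset_pct,
                "duration_pct": timing.duration_pct,
                "second_onset_pct": timing.second_onset_pct,
                "second_offset_pct": timing.second_offset_pct,
            }
        except ValueError:
            burst_timing[label] = {
                "onset_pct": None,
                "offset_pct": None,
                "duration_pct": None,
                "second_onset_pct": None,
                "second_offset_pct": None,
            }

    cci_mean: dict[str, np.ndarray] = {}
    for a_lab, b_lab in coactivation.DEFAULT_PAIRS:
        per_cycle = [
            coactivation.cci_curve(ca, cb, pair=(a_lab, b_lab)).values
            for ca, cb in zip(norm_cycles[a_lab], norm_cycles[b_lab])
        ]
        cci_mean[f"{a_lab}-{b_lab}"] = np.mean(per_cycle, axis=0)

    streams = read_quat_session(manifest.quat_csv)
    sagittal: dict[str, np.ndarray] = {}
    for site, stream in streams.items():
        ref = kinematics.calibrate_neutral(stream, cfg.calibration_window_s)
        rel = kinematics.relative_orientation(stream, ref)
        sagittal[site] = kinematics.sagittal_angle(rel)
    fs_imu = next(iter(streams.values())).fs
    gyro_z = kinematics.angular_velocity_z(streams["shank"])
    events = kinematics.detect_events(
        gyro_z, fs_imu, cfg.event_prominence_dps, cfg.event_min_separation_s
    )
    angles_mean: dict[str, np.ndarray] = {}
    hs_kin = events.heel_strikes[: n_use + 1]
    for joint, (prox, dist) in kinematics.JOINT_SEGMENTS.items():
        track = kinematics.joint_angle(
            sagittal[dist], sagittal[prox], fs_imu, joint, cfg.angle_cutoff_hz
        )
        cycles = [
            emg.time_normalize(c)
            for c in emg.segment_cycles(track.angle_deg, hs_kin)
        ]
        angles_mean[joint] = emg.mean_cycle(cycles).values
    total_time = (events.heel_strikes[-1] - events.heel_strikes[0]) / fs_imu
    params = kinematics.temporal_params(
        events,
        fs_imu,
        manifest.distance_m,
        total_time,
        mean_angle_cycles=angles_mean,
        cv_ddof=cfg.cv_ddof,
    )
    stance_end = params.stance_pct if np.isfinite(params.stance_pct) else 60.0
    slope = coactivation.slope_ratio(
        emg.NormalizedCycleSeries(values=emg_mean["SOL"]),
        emg.NormalizedCycleSeries(values=emg_mean["LG"]),
        stance_end,
    )
    return {
        "subject_id": manifest.subject_id,
        "group": manifest.group,
        "condition": manifest.condition,
        "n_cycles_used": n_use,
        "emg_mean": {k: v.tolist() for k, v in emg_mean.items()},
        "cci_mean": {k: v.tolist() for k, v in cci_mean.items()},
        "burst_timing": burst_timing,
        "slope_ratio_sol_lg": slope,
        "angles_mean": {k: v.tolist() for k, v in angles_mean.items()},
        "temporal": {
            "mean_velocity": params.mean_velocity,
            "cycle_time": params.cycle_time,
            "cycle_time_cv": params.cycle_time_cv,
            "stance_pct": params.stance_pct,
            "rom": params.rom,
        },
    }


def save_bundle(bundle: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(bundle, indent=1, sort_keys=True))


# --------------------------------------------------------------- group level


def _spm_block(curves_a: np.ndarray, curves_b: np.ndarray, alpha: float) -> dict:
    res = spm.spm_ttest2(curves_a, curves_b, alpha=alpha)
    return {
        "t_crit": res.t_crit if np.isfinite(res.t_crit) else None,
        "fwhm": res.fwhm if np.isfinite(res.fwhm) else None,
        "df": res.df,
        "clusters": [
            {
                "start_pct": float(c.start),
                "end_pct": float(c.end),
                "p": c.p_value,
                "mean_d": c.mean_d,
            }
            for c in res.clusters
        ],
    }


def _scalar_block(vals_a: list[float], vals_b: list[float]) -> dict:
    a = np.asarray(vals_a, dtype=float)
    b = np.asarray(vals_b, dtype=float)
    stat, p, kind = spm.compare_scalar(a, b, kind="t")
    try:
        d = spm.cohens_d_scalar(
            a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
        ).d
    except ZeroDivisionError:
        # degenerate variance (e.g. duplicated bundles): effect size is 0
        # for equal means, undefined otherwise
        d = 0.0 if a.mean() == b.mean() else None
    return {"statistic": stat, "p": p, "d": d, "test": kind}


def run_group_comparison(
    bundles_a: list[dict], bundles_b: list[dict], config: AnalysisConfig | None = None
) -> dict:
    """Group comparison report: SPM per waveform, scalar tests per parameter."""
    cfg = config or AnalysisConfig()
    if len(bundles_a) < 2 or len(bundles_b) < 2:
        raise ValueError("need at least 2 bundles per group")

    def stack(bundles: list[dict], section: str, key: str) -> np.ndarray:
        return np.vstack([np.asarray(b[section][key]) for b in bundles])

    report: dict = {"alpha": cfg.alpha, "n_a": len(bundles_a), "n_b": len(bundles_b)}
    for section, out_key in (
        ("emg_mean", "emg"),
        ("cci_mean", "cci"),
        ("angles_mean", "kinematics"),
    ):
        keys = bundles_a[0][section].keys()
        report[out_key] = {
            k: _spm_block(
                stack(bundles_a, section, k), stack(bundles_b, section, k), cfg.alpha
            )
            for k in keys
        }
    report["temporal"] = {}
    for param in ("mean_velocity", "cycle_time", "cycle_time_cv", "stance_pct"):
        report["temporal"][param] = _scalar_block(
            [b["temporal"][param] for b in bundles_a],
            [b["temporal"][param] for b in bundles_b],
        )
    for joint in bundles_a[0]["temporal"]["rom"]:
        report["temporal"][f"rom_{joint}"] = _scalar_block(
            [b["temporal"]["rom"][joint] for b in bundles_a],
            [b["temporal"]["rom"][joint] for b in bundles_b],
        )
    report["burst_timing"] = {}
    for muscle in bundles_a[0]["burst_timing"]:
        block = {}
        for var in ("onset_pct", "offset_pct", "duration_pct"):
            va = [b["burst_timing"][muscle][var] for b in bundles_a]
            vb = [b["burst_timing"][muscle][var] for b in bundles_b]
            va = [v for v in va if v is not None]
            vb = [v for v in vb if v is not None]
            if len(va) >= 2 and len(vb) >= 2:
                block[var] = _scalar_block(va, vb)
        report["burst_timing"][muscle] = block
    sr_a = [b["slope_ratio_sol_lg"] for b in bundles_a]
    sr_b = [b["slope_ratio_sol_lg"] for b in bundles_b]
    report["slope_ratio_sol_lg"] = _scalar_block(sr_a, sr_b)
    report["slope_ratio_sol_lg"]["mean_a"] = float(np.mean(sr_a))
    report["slope_ratio_sol_lg"]["mean_b"] = float(np.mean(sr_b))
    return report


def save_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True))
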