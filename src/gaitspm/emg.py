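"""Raw surface-EMG conditioning and gait-cycle normalization.

The processing chain mirrors the standard clinical-gait EMG pipeline:
band-pass filtering of the raw interference signal, rectification via the
magnitude of the analytic (Hilbert) signal, 6 Hz low-pass smoothing to a
linear envelope, segmentation into gait cycles at heel strikes, time
normalization of each cycle onto a fixed 0-100 % grid, and amplitude
normalization to the maximum (or median of per-cycle maxima) across a
subject's included cycles.

All filters are Butterworth and applied forward-backward (zero phase), so
burst timing is not shifted; the quoted filter order is the design order of
a single pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

GRID_N = 101  #: nodes of the 0-100 % gait-cycle grid
PCT_GRID = np.arange(GRID_N, dtype=float)  #: 0, 1, ..., 100 % of cycle


@dataclass
class EmgSession:
    """A multi-channel raw EMG recording with optional heel footswitch.

    Parameters
    ----------
    channels
        Array of shape ``(n_muscles, n_samples)``, arbitrary units.
    fs
        Sampling rate in Hz.
    muscle_labels
        One unique label per channel row (e.g. ``MG``, ``TA`` ...).
    footswitch
        Optional binary per-sample heel-contact channel.
    """

    channels: np.ndarray
    fs: float
    muscle_labels: list[str]
    footswitch: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.channels = np.atleast_2d(np.asarray(self.channels, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.muscle_labels) != self.channels.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.muscle_labels)) != len(self.muscle_labels):
            raise ValueError("muscle labels must be unique")
        if self.footswitch is not None:
            self.footswitch = np.asarray(self.footswitch)
            if self.footswitch.shape[0] != self.channels.shape[1]:
                raise ValueError("footswitch length must match channels")

    def channel(self, label: str) -> np.ndarray:
        return self.channels[self.muscle_labels.index(label)]


@dataclass
class EnvelopeSeries:
    """A non-negative amplitude envelope sampled at ``fs``."""

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("envelope values must be non-negative")


@dataclass
class NormalizedCycleSeries:
    """A waveform resampled onto the fixed 101-node 0-100 % cycle grid."""

    values: np.ndarray
    grid: np.ndarray = field(default_factory=lambda: PCT_GRID.copy())

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.grid = np.asarray(self.grid, dtype=float)
        if self.values.shape != (GRID_N,):
            raise ValueError(f"values must have length {GRID_N}")
        if self.grid.shape != (GRID_N,):
            raise ValueError(f"grid must have length {GRID_N}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")


def bandpass(
    raw: np.ndarray,
    fs: float,
    low_hz: float = 20.0,
    high_hz: float = 500.0,
    order: int = 5,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass of a raw EMG channel.

    ``order`` is the per-pass design order; the forward-backward
    application doubles the effective roll-off and cancels phase delay.
    """
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw signal contains non-finite samples")
    if fs <= 2 * high_hz:
        raise ValueError(
            f"fs={fs} cannot realize a {high_hz} Hz band edge (need fs > {2 * high_hz})"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, raw)


def rectify(filtered: np.ndarray) -> np.ndarray:
    """Rectification as the magnitude of the analytic (Hilbert) signal."""
    filtered = np.asarray(filtered, dtype=float)
    if filtered.size == 0:
        raise ValueError("empty input")
    return np.abs(signal.hilbert(filtered))


def envelope(
    filtered: np.ndarray, fs: float, cutoff_hz: float = 6.0, order: int = 4
) -> EnvelopeSeries:
    """Linear envelope: analytic-signal magnitude low-passed at 6 Hz.

    Tiny negative values produced by the zero-phase smoothing are clipped
    to zero so the envelope honours its non-negativity invariant.
    """
    rect = rectify(filtered)
    sos = signal.butter(order, cutoff_hz, btype="lowpass", fs=fs, output="sos")
    smoothed = signal.sosfiltfilt(sos, rect)
    return EnvelopeSeries(values=np.clip(smoothed, 0.0, None), fs=fs)


def segment_cycles(series: np.ndarray, heel_strikes: np.ndarray) -> list[np.ndarray]:
    """Split a per-sample series into gait cycles at heel-strike indices.

    Cycle ``k`` spans ``[HS_k, HS_{k+1})``; ``len(heel_strikes) - 1``
    cycles are returned.
    """
    series = np.asarray(series)
    hs = np.asarray(heel_strikes, dtype=int)
    if hs.size < 2:
        raise ValueError("need at least two heel strikes to delimit a cycle")
    if np.any(np.diff(hs) <= 0):
        raise ValueError("heel strikes must be strictly increasing")
    if hs[0] < 0 or hs[-1] > series.shape[0]:
        raise ValueError("heel strikes outside the recording")
    return [series[hs[k] : hs[k + 1]] for k in range(hs.size - 1)]


def time_normalize(cycle: np.ndarray) -> NormalizedCycleSeries:
    """Linearly resample one cycle onto the 101-node 0-100 % grid."""
    cycle = np.asarray(cycle, dtype=float)
    if cycle.size < 2:
        raise ValueError("cycle must contain at least 2 samples")
    x = np.linspace(0.0, 100.0, cycle.size)
    return NormalizedCycleSeries(values=np.interp(PCT_GRID, x, cycle))


def amplitude_normalize(
    cycles: list[NormalizedCycleSeries], mode: str = "max"
) -> tuple[list[NormalizedCycleSeries], float]:
    """Amplitude-normalize a subject's cycles for one muscle.

    mode="max"
        Divide by the single maximum over all included cycles; the global
        maximum of the output is exactly 1.
    mode="median"
        Divide by the median of the per-cycle maxima (robust alternative
        when an outlier cycle would depress all other normalized values).

    Returns the normalized cycles and the reference value used.
    """
    if not cycles:
        raise ValueError("need at least one cycle")
    peaks = np.array([c.values.max() for c in cycles])
    if mode == "max":
        ref = float(peaks.max())
    elif mode == "median":
        ref = float(np.median(peaks))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if ref == 0:
        raise ValueError("all-zero normalization reference: dead channel?")
    out = [NormalizedCycleSeries(values=c.values / ref) for c in cycles]
    return out, ref


def mean_cycle(cycles: list[NormalizedCycleSeries]) -> NormalizedCycleSeries:
    """Node-wise arithmetic mean of equally gridded cycles."""
    if not cycles:
        raise ValueError("need at least one cycle")
    g0 = cycles[0].grid
    for c in cycles[1:]:
        if not np.array_equal(c.grid, g0):
            raise ValueError("mismatched grids")
    return NormalizedCycleSeries(
        values=np.mean([c.values for c in cycles], axis=0), grid=g0.copy()
    )
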