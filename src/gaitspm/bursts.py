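"""EMG burst on/offset detection by 1D k-means clustering.

A muscle's rectified EMG amplitude is partitioned into three clusters; the
lowest cluster is taken as inactivity and samples in either upper cluster
as active. Maximal active runs become burst intervals, which are then
cleaned with two rules applied in order: bursts shorter than 5 ms are
discarded, and bursts separated by gaps shorter than 125 ms are merged.
Burst timing is finally expressed in % of each gait cycle, with circular
averaging so bursts spanning the heel strike are handled correctly.

Clustering operates on the per-sample rectified (analytic-magnitude)
signal rather than the 6 Hz envelope; the very short 5 ms discard rule
only makes sense on an unsmoothed amplitude series. The envelope can be
substituted by simply passing it as the input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

MIN_BURST_MS = 5.0
MERGE_GAP_MS = 125.0
#: stance-to-swing transition window (% cycle) searched for a second
#: rectus femoris burst
SECOND_BURST_WINDOW = (45.0, 75.0)


@dataclass
class BurstTrain:
    """Per-muscle activity intervals ``[onset, offset)`` in samples."""

    intervals: list[tuple[int, int]]
    muscle_label: str
    fs: float

    def __post_init__(self) -> None:
        prev_end = -1
        for on, off in self.intervals:
            if on >= off:
                raise ValueError(f"interval ({on}, {off}) has onset >= offset")
            if on <= prev_end:
                raise ValueError("intervals must be sorted and disjoint")
            prev_end = off

    def durations_ms(self) -> np.ndarray:
        return np.array([(off - on) / self.fs * 1e3 for on, off in self.intervals])


@dataclass
class BurstTiming:
    """Mean burst on/offset/duration in % gait cycle, with per-cycle values."""

    onset_pct: float
    offset_pct: float
    duration_pct: float
    per_cycle: list[dict] = field(default_factory=list)
    second_onset_pct: float | None = None
    second_offset_pct: float | None = None


def kmeans_1d(values: np.ndarray, k: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Exact 1D k-means: globally optimal and deterministic.

    In one dimension the optimal k-means clusters are contiguous in
    sorted order, so the minimum within-cluster sum of squares is found
    exactly by dynamic programming over split positions (divide-and-
    conquer exploiting the monotonicity of optimal splits, O(k n log n)).
    No random initialization is involved and no local optimum can be
    returned. Centers come back sorted ascending with per-sample labels.
    """
    values = np.asarray(values, dtype=float).ravel()
    n = values.size
    if np.unique(values).size < k:
        raise ValueError(f"need at least {k} distinct values")
    order = np.argsort(values, kind="stable")
    x = values[order]
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def seg_cost(a: np.ndarray, b: int) -> np.ndarray:
        """Within-cluster SSE of sorted points a..b inclusive (a vectorized)."""
        s = cs[b + 1] - cs[a]
        s2 = cs2[b + 1] - cs2[a]
        m = b + 1 - a
        return s2 - s * s / m

    d_prev = cs2[1:] - (cs[1:] ** 2) / np.arange(1, n + 1)  # 1-cluster costs
    splits = np.zeros((k, n), dtype=int)
    for layer in range(1, k):
        d_cur = np.full(n, np.inf)
        # monotone optimal splits: divide and conquer over i with an
        # explicit stack of (i_lo, i_hi, j_lo, j_hi) segments
        stack = [(layer, n - 1, layer - 1, n - 2)]
        while stack:
            i_lo, i_hi, j_lo, j_hi = stack.pop()
            if i_lo > i_hi:
                continue
            mid = (i_lo + i_hi) // 2
            js = np.arange(j_lo, min(j_hi, mid - 1) + 1)
            costs = d_prev[js] + seg_cost(js + 1, mid)
            best = int(js[np.argmin(costs)])
            d_cur[mid] = costs[best - j_lo]
            splits[layer, mid] = best
            stack.append((i_lo, mid - 1, j_lo, best))
            stack.append((mid + 1, i_hi, best, j_hi))
        d_prev = d_cur

    # backtrack cluster boundaries on the sorted data
    bounds = np.empty(k + 1, dtype=int)
    bounds[k] = n
    i = n - 1
    for layer in range(k - 1, 0, -1):
        j = splits[layer, i]
        bounds[layer] = j + 1
        i = j
    bounds[0] = 0
    centers = np.array(
        [x[bounds[j] : bounds[j + 1]].mean() for j in range(k)]
    )
    labels_sorted = np.repeat(np.arange(k), np.diff(bounds))
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return centers, labels


def detect_activity(
    rectified: np.ndarray, fs: float, muscle_label: str = "", k: int = 3
) -> BurstTrain:
    """Raw burst intervals from a rectified EMG amplitude series.

    A sample is active iff k-means assigns it to either of the two upper
    amplitude clusters. A silent channel (fewer than ``k`` distinct
    amplitudes) yields an empty train with a warning.
    """
    rectified = np.asarray(rectified, dtype=float)
    if np.any(rectified < 0):
        raise ValueError("input must be rectified (non-negative)")
    try:
        _, labels = kmeans_1d(rectified, k=k)
    except ValueError:
        warnings.warn(f"channel {muscle_label!r} is silent; no bursts detected")
        return BurstTrain(intervals=[], muscle_label=muscle_label, fs=fs)
    active = labels >= 1
    padded = np.concatenate(([False], active, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    intervals = [(int(edges[i]), int(edges[i + 1])) for i in range(0, edges.size, 2)]
    return BurstTrain(intervals=intervals, muscle_label=muscle_label, fs=fs)


def clean(
    train: BurstTrain,
    min_burst_ms: float = MIN_BURST_MS,
    merge_gap_ms: float = MERGE_GAP_MS,
) -> BurstTrain:
    """Apply the discard-then-merge cleaning rules.

    Step 1 removes every burst shorter than ``min_burst_ms``; step 2 merges
    consecutive bursts separated by less than ``merge_gap_ms``. The order
    matters (a short burst bridging two others is dropped before it can
    merge them) and the operation is idempotent.
    """
    min_samp = min_burst_ms / 1e3 * train.fs
    gap_samp = merge_gap_ms / 1e3 * train.fs
    kept = [(on, off) for on, off in train.intervals if (off - on) >= min_samp]
    merged: list[tuple[int, int]] = []
    for on, off in kept:
        if merged and (on - merged[-1][1]) < gap_samp:
            merged[-1] = (merged[-1][0], off)
        else:
            merged.append((on, off))
    return BurstTrain(intervals=merged, muscle_label=train.muscle_label, fs=train.fs)


def _circmean_pct(values: np.ndarray) -> float:
    """Circular mean of % gait-cycle positions (period 100)."""
    return float(stats.circmean(np.asarray(values, dtype=float), high=100.0, low=0.0))


def cycle_timing(
    train: BurstTrain,
    heel_strikes: np.ndarray,
    second_burst_window: tuple[float, float] | None = None,
) -> BurstTiming:
    """Burst timing per gait cycle and its wrap-aware mean.

    For each cycle the primary burst is the longest interval overlapping
    it; onset and offset are converted to % of that cycle, wrapping so a
    burst spanning the heel strike reports its onset in late % and offset
    in early %. Onset/offset means over cycles are circular (period
    100 %); duration is averaged linearly. Cycles with no burst are
    excluded from the means.

    When ``second_burst_window`` is given (used for rectus femoris), a
    distinct non-primary interval whose midpoint falls inside the window
    is reported as a second burst.
    """
    hs = np.asarray(heel_strikes, dtype=int)
    if hs.size < 2:
        raise ValueError("need at least one full cycle")
    per_cycle: list[dict] = []
    for k in range(hs.size - 1):
        h0, h1 = hs[k], hs[k + 1]
        span = h1 - h0
        overlapping = [
            (on, off) for on, off in train.intervals if on < h1 and off > h0
        ]
        if not overlapping:
            per_cycle.append({"onset": None, "offset": None, "duration": None})
            continue
        on, off = max(overlapping, key=lambda iv: iv[1] - iv[0])
        onset_pct = (on - h0) / span * 100.0 % 100.0
        offset_pct = (off - h0) / span * 100.0 % 100.0
        duration_pct = min((off - on) / span * 100.0, 100.0)
        entry = {"onset": onset_pct, "offset": offset_pct, "duration": duration_pct}
        if second_burst_window is not None:
            lo, hi = second_burst_window
            candidates = [
                iv
                for iv in overlapping
                if iv != (on, off)
                and lo <= ((iv[0] + iv[1]) / 2 - h0) / span * 100.0 <= hi
            ]
            if candidates:
                s_on, s_off = max(candidates, key=lambda iv: iv[1] - iv[0])
                entry["second_onset"] = (s_on - h0) / span * 100.0 % 100.0
                entry["second_offset"] = (s_off - h0) / span * 100.0 % 100.0
        per_cycle.append(entry)

    onsets = [c["onset"] for c in per_cycle if c["onset"] is not None]
    if not onsets:
        raise ValueError("no burst found in any cycle")
    offsets = [c["offset"] for c in per_cycle if c["offset"] is not None]
    durations = [c["duration"] for c in per_cycle if c["duration"] is not None]
    s_ons = [c["second_onset"] for c in per_cycle if "second_onset" in c]
    s_offs = [c["second_offset"] for c in per_cycle if "second_offset" in c]
    return BurstTiming(
        onset_pct=_circmean_pct(onsets),
        offset_pct=_circmean_pct(offsets),
        duration_pct=float(np.mean(durations)),
        per_cycle=per_cycle,
        second_onset_pct=_circmean_pct(s_ons) if s_ons else None,
        second_offset_pct=_circmean_pct(s_offs) if s_offs else None,
    )
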