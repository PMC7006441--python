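"""Antagonist co-contraction index (CCI) curves and the SOL/LG slope ratio.

The CCI at gait-cycle node ``i`` compares the amplitude-normalized
envelopes of an antagonist pair::

    CCI_i = (LEMG_i / HEMG_i) * (LEMG_i + HEMG_i)

where ``LEMG`` is the less active and ``HEMG`` the more active muscle at
that node. CCI is bounded in [0, 2]: 2 only when both muscles sit at their
normalized maximum of 1, 0 whenever either muscle is silent. The
less/more-active roles are resolved per node, so the curve is symmetric in
its two inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .emg import NormalizedCycleSeries

#: Antagonist pairs crossing the ankle and knee used in the group analysis.
DEFAULT_PAIRS: tuple[tuple[str, str], ...] = (
    ("MG", "TA"),
    ("LG", "TA"),
    ("SOL", "TA"),
    ("VL", "BF"),
    ("VM", "ST"),
    ("LG", "VL"),
    ("MG", "VM"),
)

_NORM_TOL = 1e-9


@dataclass
class CciSeries:
    """Per-node co-contraction index for one antagonist pair."""

    pair: tuple[str, str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -_NORM_TOL) or np.any(self.values > 2 + _NORM_TOL):
            raise ValueError("CCI values must lie in [0, 2]")


def cci_curve(
    a: NormalizedCycleSeries,
    b: NormalizedCycleSeries,
    pair: tuple[str, str] = ("A", "B"),
) -> CciSeries:
    """Co-contraction index curve for two amplitude-normalized envelopes.

    Inputs must be normalized to [0, 1]; values outside that range (beyond
    numerical tolerance) indicate un-normalized input and raise. Nodes
    where the more active muscle is exactly zero get CCI 0, the continuous
    limit of the formula.
    """
    va, vb = a.values, b.values
    for v in (va, vb):
        if np.any(v < -_NORM_TOL) or np.any(v > 1 + _NORM_TOL):
            raise ValueError("inputs must be amplitude-normalized to [0, 1]")
    low = np.minimum(va, vb)
    high = np.maximum(va, vb)
    with np.errstate(divide="ignore", invalid="ignore"):
        cci = np.where(high > 0, low / high * (low + high), 0.0)
    return CciSeries(pair=pair, values=np.clip(cci, 0.0, 2.0))


def slope_ratio(
    sol: NormalizedCycleSeries,
    lg: NormalizedCycleSeries,
    stance_end_pct: float,
) -> float:
    """SOL/LG envelope slope ratio over the first half of stance.

    Fits a least-squares line to each muscle's mean envelope over the
    cycle nodes in ``[0, stance_end_pct / 2]`` and returns
    ``slope(SOL) / slope(LG)``. A decreased ratio indicates a relative
    shift of recruitment from soleus toward lateral gastrocnemius.
    """
    if not (0 < stance_end_pct <= 100):
        raise ValueError("stance_end_pct must lie in (0, 100]")
    mask = sol.grid <= stance_end_pct / 2.0
    x = sol.grid[mask]
    s_sol = np.polyfit(x, sol.values[mask], 1)[0]
    s_lg = np.polyfit(x, lg.values[mask], 1)[0]
    if abs(s_lg) < 1e-12:
        raise ZeroDivisionError("LG slope is zero; slope ratio undefined")
    return float(s_sol / s_lg)
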