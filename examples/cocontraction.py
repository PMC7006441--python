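"""Co-contraction index curve and SOL/LG slope ratio.

Builds two amplitude-normalized envelope curves for an antagonist pair
(plantar flexor vs dorsiflexor), evaluates the per-node co-contraction
index CCI = (L/H)(L+H), and computes the slope ratio of two calf-muscle
envelopes over the first half of stance. CCI is 0 where either muscle is
silent and reaches 2 only where both sit at their normalized maximum.
"""

import numpy as np

from gaitspm import coactivation
from gaitspm.emg import NormalizedCycleSeries, PCT_GRID

# plantar flexor active 10-45 %, dorsiflexor active around heel strike
pf = np.exp(-0.5 * ((PCT_GRID - 28) / 10.0) ** 2)
df = np.clip(
    np.exp(-0.5 * ((PCT_GRID - 2) / 6.0) ** 2)
    + np.exp(-0.5 * ((PCT_GRID - 85) / 10.0) ** 2),
    0.0,
    1.0,
)
cci = coactivation.cci_curve(
    NormalizedCycleSeries(values=pf), NormalizedCycleSeries(values=df), ("MG", "TA")
)
peak_node = int(np.argmax(cci.values))
print(f"CCI range: {cci.values.min():.3f} - {cci.values.max():.3f} (bounds 0-2)")
print(f"peak co-contraction at {peak_node} % of cycle: {cci.values[peak_node]:.3f}")

# slope ratio: soleus rising at half the lateral gastrocnemius rate during
# early stance indicates a recruitment shift toward the gastrocnemius
ramp = PCT_GRID / 100.0
sol = NormalizedCycleSeries(values=0.5 * ramp)
lg = NormalizedCycleSeries(values=1.0 * ramp)
ratio = coactivation.slope_ratio(sol, lg, stance_end_pct=60.0)
print(f"SOL/LG slope ratio over first half of stance: {ratio:.2f}")
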