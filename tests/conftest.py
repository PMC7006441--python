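import numpy as np
import pytest

from gaitspm import synthio
from gaitspm.emg import NormalizedCycleSeries


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def short_plan():
    """20-cycle gait plan with mild timing variability."""
    return synthio.GaitPlan(
        n_cycles=20, cycle_time_mean=1.1, cycle_time_cv=2.0, stance_fraction=60.0
    )


@pytest.fixture(scope="session")
def single_burst_channel(short_plan):
    """EMG channel with one 10-40 % burst per cycle (peak 1.0, floor 0.05)."""
    profile = synthio.MuscleProfile("MG", [(10.0, 40.0, 1.0)], noise_floor=0.05)
    channel, truth = synthio.generate_emg_channel(profile, short_plan, 1500.0, seed=7)
    return channel, truth


def cycle_series(values):
    return NormalizedCycleSeries(values=np.asarray(values, dtype=float))


@pytest.fixture(scope="session")
def ramp_cycle():
    return cycle_series(np.linspace(0.0, 1.0, 101))
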