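import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ionideal as ii

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

FS = 5e4


@pytest.fixture(scope="session")
def std_filter():
    """The 4-pole Bessel filter at normalized cutoff 0.1, 50 kHz (m = 11)."""
    return ii.make_filter(4, 0.1, FS)


@pytest.fixture(scope="session")
def coarse_filter():
    """A short-kernel filter for brute-force-sized problems."""
    return ii.make_filter(4, 0.2, 1e3)


@pytest.fixture(scope="session")
def store():
    """Shared in-memory critical-value cache (keys include the seed)."""
    return ii.CritvalStore()


@pytest.fixture(scope="session")
def two_state_sim(std_filter, store):
    """A simulated two-state (0 / 1 nS) trace with its idealization.

    Alternating gating every 256 samples, sigma = 0.1 nS, n = 8192; idealized
    with the above-filter-length detector and locally deconvolved.
    """
    fs = std_filter.sample_rate
    n = 8192
    period = 256
    changes = np.arange(period, n - period // 2, period) / fs
    levels = np.array([i % 2 for i in range(len(changes) + 1)], dtype=float)
    truth = ii.StepSignal(
        change_times=changes, levels=levels, start=0.0, end=n / fs
    )
    trace = ii.simulate_trace(truth, std_filter, n, sigma=0.1, seed=2024)
    config = ii.MethodConfig(method="jsmurf", r=300, seed=17)
    fit = ii.jsmurf(trace, std_filter, config, store)
    ideal = ii.local_deconvolution(trace, std_filter, fit)
    return {"truth": truth, "trace": trace, "fit": fit, "ideal": ideal}
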