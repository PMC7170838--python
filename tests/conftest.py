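import numpy as np
import pytest

import orawave as ow


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-parameter cohort shared across read-only tests."""
    return ow.simulate_cohort(ow.SimConfig(n_eyes=24, seed=11))


@pytest.fixture(scope="session")
def clean_trace():
    """One noise-free trace with a known planted retro magnitude of 30."""
    cfg = ow.SimConfig(noise_sd=0.0, seed=5)
    rng = np.random.default_rng(0)
    trace = ow.simulate_waveform(cfg, 30.0, rng, heights=(611.54, 526.29))
    return cfg, trace
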