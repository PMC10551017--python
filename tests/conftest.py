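import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from neurograft import RawTraceSet, SimConfig, simulate_traces


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_raw(rng) -> RawTraceSet:
    """20 unstructured random traces, T=60, with compartment labels."""
    traces = {i: 100.0 + 15.0 * rng.standard_normal(60) for i in range(20)}
    comp = {i: ("host" if i < 12 else "implant") for i in range(20)}
    return RawTraceSet(traces=traces, compartment_of=comp)


@pytest.fixture
def planted_raw():
    """Two planted communities spanning the host-implant divide, SNR 5."""
    cfg = SimConfig(
        n_host=20,
        n_implant=12,
        n_frames=300,
        communities=[((0, 1, 2, 20, 21), 0.08), ((5, 6, 7, 25, 26), 0.08)],
        background_event_rate=0.02,
        transient_amplitude=20.0,
        noise_sd=4.0,
        seed=11,
    )
    raw, truth = simulate_traces(cfg)
    return cfg, raw, truth
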