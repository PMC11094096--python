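import numpy as np
import pytest

from slicephys import synthgen as sg
from slicephys.kernels import KernelSpec


@pytest.fixture
def ampa() -> KernelSpec:
    return KernelSpec(40.0, 0.5, 5.0)


@pytest.fixture
def nmda() -> KernelSpec:
    return KernelSpec(10.0, 5.0, 80.0)


@pytest.fixture
def noiseless_mepsc():
    """A short noiseless mEPSC trace with its ground truth."""
    cfg = sg.SimConfig(seed=6, duration=12_000.0, event_rate=1.0, noise_sd=0.0)
    sweep, gt = sg.simulate_event_trace(cfg, "mEPSC")
    return cfg, sweep, gt


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
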