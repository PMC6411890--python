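import numpy as np
import pytest

from meanet.config import SimConfig
from meanet.synth import simulate_assembly_device


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def assembly_device():
    """30 active electrodes in 3 planted assemblies of 10 (fixed seed)."""
    cfg = SimConfig(n_electrodes=30, duration_s=600.0, seed=42,
                    n_assemblies=3, assembly_size=10, copy_prob=0.9,
                    jitter_sd_s=0.005, background_rate_hz=0.3)
    return simulate_assembly_device(cfg, mother_rate_hz=3.0)


def random_train(rng, rate_hz, T):
    n = rng.poisson(rate_hz * T)
    return np.sort(rng.uniform(0.0, T, size=n))
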