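import numpy as np
import pytest

from brainclock import SimConfig, make_fixture, simulate


@pytest.fixture(scope="session")
def mirror_small():
    return make_fixture("mirror-small")


@pytest.fixture(scope="session")
def repetition_small():
    return make_fixture("repetition-small")


@pytest.fixture(scope="session")
def noise_only():
    return make_fixture("noise-only")


@pytest.fixture(scope="session")
def small_sim_with_truth():
    """Mid-sized noiseless mirror simulation with ground truth attached."""
    cfg = SimConfig(
        n_neurons=15, delta=2000, n_cycles=80, quiet_width=300, quiet_offset=200,
        mode="mirror", participation_prob=0.5, jitter_sd=0.0,
        burst_size_range=(2, 3), noise_rate=0.0, seed=7,
    )
    return simulate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
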