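import numpy as np
import pytest

from fincrawl.crawl_simulator import (
    SimConfig,
    SuckerModel,
    build_protocol,
    simulate,
)


@pytest.fixture(scope="session")
def default_model():
    return SuckerModel()


@pytest.fixture(scope="session")
def forward_recording(default_model):
    """5 noiseless forward crawl cycles at default parameters."""
    cfg = SimConfig(n_cycles=5, noise_sigma=0.0, seed=0)
    return simulate(default_model, build_protocol("forward"), cfg)


@pytest.fixture(scope="session")
def backward_recording(default_model):
    cfg = SimConfig(n_cycles=5, noise_sigma=0.0, seed=0)
    return simulate(default_model, build_protocol("backward"), cfg)


@pytest.fixture(scope="session")
def forward_profile(forward_recording):
    from fincrawl.axial_kinematics import analyze_recording

    return analyze_recording(forward_recording)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
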