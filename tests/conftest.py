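import numpy as np
import pytest

from cafkit.synthetic import SimConfig


@pytest.fixture()
def default_config():
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def small_afm_config():
    """Short noiseless curves for fast fitting tests."""
    cfg = SimConfig(seed=2)
    cfg.afm_spec.force_noise_nN = 0.0
    cfg.afm_spec.n_samples = 200
    return cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
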