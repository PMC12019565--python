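import numpy as np
import pytest

from nanorheo.forward_model import ChannelNoise, MembraneModel, RampSpec
from nanorheo.lockin import ShearDrive


@pytest.fixture
def model():
    """Default noiseless DOPC-like membrane."""
    return MembraneModel()


@pytest.fixture
def drive():
    """25 kHz / 5 nm shear drive."""
    return ShearDrive()


@pytest.fixture
def ramp():
    """30 nm approach at 30 nm/s, 2 kHz sampling, contact at 20 nm."""
    return RampSpec()


@pytest.fixture
def noisy_model(model):
    """Realistic channel noise: 10 pN on F_N, 5% relative + 0.05 pN on F_S."""
    return model.with_(
        noise=ChannelNoise(sigma_fn=10e-12, sigma_fs=0.05e-12,
                           sigma_fs_rel=0.05, sigma_theta=1.0)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
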