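import numpy as np
import pytest

from ratecal.models import (
    GaussianChannelModel,
    GaussianEnsembleSpec,
    PointProcessChannelModel,
    PointProcessEnsembleSpec,
    sample_channel_ensemble,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gaussian_channel():
    return GaussianChannelModel(xi=3.0, eta=np.array([8.0, -2.0]), Z=350.0)


@pytest.fixture
def spiking_neuron():
    return PointProcessChannelModel(beta=np.log(5.0), alpha=np.array([1.5, 0.5]),
                                    delta=0.001)


@pytest.fixture
def gaussian_ensemble(rng):
    return sample_channel_ensemble(GaussianEnsembleSpec(), 8, rng)


@pytest.fixture
def spiking_ensemble(rng):
    return sample_channel_ensemble(PointProcessEnsembleSpec(v_max=0.9), 8, rng)
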