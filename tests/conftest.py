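import numpy as np
import pytest

from rnnpb.network import ModelWeights, NetworkConfig, PBVector
from rnnpb.trajectories import DatasetProtocol, make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    return NetworkConfig(n_in=2, n_d=3, n_v=2, n_pb1=1, n_pb2=2)


@pytest.fixture
def tiny_weights(tiny_config, rng):
    return ModelWeights.random(tiny_config, rng, scale=0.5)


@pytest.fixture
def tiny_pb(tiny_config, rng):
    return PBVector(
        rho1=rng.normal(size=tiny_config.n_pb1),
        rho2=rng.normal(size=tiny_config.n_pb2),
    )


@pytest.fixture(scope="session")
def default_dataset():
    """The standard 20-sequence training set (5 reps x 2 colors x 2 curves)."""
    return make_dataset(DatasetProtocol(base_seed=1))
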