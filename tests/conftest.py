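import numpy as np
import pytest

from streamclass import GNShape, MixtureState


@pytest.fixture
def norm_shape():
    return GNShape(beta=2.0, sigma=1.0)


@pytest.fixture
def heavy_shape():
    return GNShape(beta=0.5, sigma=1.0)


@pytest.fixture
def two_class_state(norm_shape):
    return MixtureState(
        centroids=np.array([0.0, 5.0]),
        mixing=np.array([0.95, 0.05]),
        shape=norm_shape,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
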