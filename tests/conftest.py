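import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def blobs():
    """The standard synthetic task: 3 Gaussian classes in 20 dims,
    600 training / 300 test samples, separation 6, noise 0.05."""
    from glsnn import make_blobs

    return make_blobs(n_per_class=200, dim=20, n_classes=3,
                      separation=6.0, noise_sd=0.05, seed=0)


def random_small_net(rng, max_layers=4, max_width=8):
    """A random architecture with modest weights for oracle comparisons."""
    from glsnn import Network

    L = int(rng.integers(2, max_layers + 1))
    sizes = [int(rng.integers(1, max_width + 1)) for _ in range(L)]
    weights = [
        rng.standard_normal((sizes[l], sizes[l + 1])) * 0.5 for l in range(L - 1)
    ]
    return Network(sizes, weights)
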