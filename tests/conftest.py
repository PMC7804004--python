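import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ctnets

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_atlas():
    """20 regions, two ground-truth modules, homolog pairs (i, i+10)."""
    return ctnets.make_atlas(20, [10, 10])


@pytest.fixture(scope="session")
def small_dataset(small_atlas):
    spec = ctnets.CovarianceSpec(
        n_regions=20,
        module_sizes=(10, 10),
        rho_within=0.5,
        rho_between=0.15,
        rho_homolog=0.6,
        rho_diffuse=0.2,
    )
    return ctnets.simulate_group(
        spec, ctnets.CovariateModel(), 100, seed=7, atlas=small_atlas
    )


def random_graph(n, p, seed):
    """Erdos-Renyi adjacency as a plain symmetric 0/1 matrix."""
    g = np.random.default_rng(seed)
    a = np.triu((g.random((n, n)) < p), 1)
    a = (a | a.T).astype(np.uint8)
    return a
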