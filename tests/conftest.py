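import numpy as np
import pytest

from trex3d.model_core import ContactMatrix, CovariateSet, Structure3D
from trex3d.simulator import SimulationConfig, make_gold_structure, simulate_dataset


@pytest.fixture(scope="session")
def gold():
    return make_gold_structure(n=43, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_structure(rng):
    return Structure3D(rng.standard_normal((10, 3)))


@pytest.fixture(scope="session")
def small_dataset(gold):
    """A moderately informative NRE dataset on the gold structure."""
    cfg = SimulationConfig(model="NRE", pi=0.0)
    counts, cov = simulate_dataset(gold, cfg, seed=7)
    return counts, cov


def random_instance(rng, n=8, lam_scale=3.0):
    """A small random structure + counts + covariates for oracle checks."""
    structure = Structure3D(rng.standard_normal((n, 3)))
    cov = CovariateSet(rng.uniform(0.2, 0.3, n), rng.uniform(0.4, 0.5, n),
                       rng.uniform(0.9, 1.0, n))
    counts = rng.poisson(lam_scale, (n, n))
    counts = np.triu(counts, 1)
    counts = counts + counts.T
    return structure, ContactMatrix(counts), cov
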