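import numpy as np
import pytest

import circumfit as cf
from circumfit.bcfa import BcfaConfig


@pytest.fixture(scope="session")
def population():
    return cf.default_population()


@pytest.fixture(scope="session")
def octant_data(population):
    """Standardized octant scales at the study sample size."""
    return cf.standardize(cf.simulate_scales(population, 822, seed=20))


@pytest.fixture(scope="session")
def mcfa_solution(octant_data):
    return cf.fit_mcfa(octant_data, cf.ideal_circumplex_pattern())


@pytest.fixture(scope="session")
def fast_bcfa(octant_data):
    """A short, reduced-precision posterior shared across sampler tests."""
    cfg = BcfaConfig(
        seed=11, max_iterations=3000, min_iterations=1000, check_every=500,
        psr_target=1.05,
    )
    return cf.fit_bcfa(octant_data, cf.ideal_circumplex_pattern(), cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
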