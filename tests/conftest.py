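import numpy as np
import pytest

from szest import (
    CohortSpec,
    PriorConfig,
    SFModelParams,
    StrategyConfig,
    build_10_2_grid,
    default_domain,
    displace_locations,
    gen_cohort,
    make_normative_map,
)


@pytest.fixture(scope="session")
def grid():
    return build_10_2_grid()


@pytest.fixture(scope="session")
def displaced_grid():
    return displace_locations(build_10_2_grid())


@pytest.fixture(scope="session")
def normative(displaced_grid):
    return make_normative_map(displaced_grid)


@pytest.fixture(scope="session")
def domain():
    return default_domain()


@pytest.fixture
def prior_cfg():
    return PriorConfig()


@pytest.fixture
def sf_params():
    return SFModelParams()


@pytest.fixture
def strategy_cfg():
    return StrategyConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """4 healthy + 4 glaucoma eyes, fixed seed — shared across tests."""
    return gen_cohort(CohortSpec(n_healthy=4, n_glaucoma=4,
                                 severity_mix=(0.25, 0.25, 0.5), seed=7))
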