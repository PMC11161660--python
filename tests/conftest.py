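import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from sidetraj import (
    CohortConfig,
    ModelSpec,
    ObservationModelConfig,
    PopulationParams,
    generate_cohort,
)


@pytest.fixture(scope="session")
def wiener_spec():
    return ModelSpec.from_variant(2)


@pytest.fixture(scope="session")
def ou_spec():
    return ModelSpec.from_variant(4)


@pytest.fixture(scope="session")
def obs_cfg():
    return ObservationModelConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """10 individuals, no structural zeros, balanced 6-observation series."""
    cfg = CohortConfig(
        n_individuals=10,
        zero_fraction=0.0,
        fixed_obs_count=6,
        gap_median_days=14.0,
        gap_log_sd=0.8,
        true_pop=PopulationParams(mu=np.array([-1.0, -1.2]), tau=np.array([1.0, 0.5]), sigma_y=2.0),
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
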