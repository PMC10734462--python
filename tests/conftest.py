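import pytest
from hypothesis import settings

from ferroscan.simulate import SimulationConfig, simulate_cohort

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")


@pytest.fixture(scope="session")
def small_cohort():
    """8-genome cohort (2 per group) at the default study conditions."""
    return simulate_cohort(SimulationConfig(seed=1, n_per_group=2))


@pytest.fixture(scope="session")
def medium_cohort():
    """12-genome cohort used by clustering and phylogeny tests."""
    return simulate_cohort(SimulationConfig(seed=2, n_per_group=3))
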