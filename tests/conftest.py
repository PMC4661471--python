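import pytest

from methvar import FragmentVariabilityModel
from methvar.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def study():
    """A small synthetic cohort study with planted ground truth."""
    return simulate_study(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def cohort(study):
    return study.to_cohort()


@pytest.fixture(scope="session")
def results(cohort):
    return FragmentVariabilityModel(cohort).fit()
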