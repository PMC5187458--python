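import pytest

from wolfhound_dcm.synthetic_data import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """A mid-sized cohort at the default (study-like) configuration."""
    return simulate_cohort(SimulationConfig(n_dogs=2000, seed=11))


@pytest.fixture(scope="session")
def default_cohort_with_truth():
    return simulate_cohort(
        SimulationConfig(n_dogs=2000, seed=12), return_truth=True
    )
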