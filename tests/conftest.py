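import pytest

from methyldyn import (
    SimulationConfig,
    simulate_generations,
    spreading_cohort_config,
)


@pytest.fixture(scope="session")
def default_sim():
    """Full multi-generation cohort at default (study) conditions."""
    return simulate_generations(SimulationConfig(), seed=101)


@pytest.fixture(scope="session")
def spread_sim():
    """Spreading cohort: every arm gene seeded, 1G reference + four 9G."""
    return simulate_generations(spreading_cohort_config(), seed=202)


@pytest.fixture(scope="session")
def uniform_sim():
    """Control cohort with spatially uniform (non-spreading) gain."""
    return simulate_generations(
        spreading_cohort_config(spread_mode="uniform"), seed=202
    )
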