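import pytest

from radeff import (
    LIMA_2017_PROFILE,
    PipelineConfig,
    TrialConfig,
    analyze_trial,
    generate_trial,
    generate_weather,
)
from radeff.weather import DEFAULT_PLANTING_DATE


@pytest.fixture(scope="session")
def flat_weather():
    """141-day weather at the monthly means (no day-to-day dispersion)."""
    return generate_weather(
        LIMA_2017_PROFILE, DEFAULT_PLANTING_DATE, 141, seed=0, dispersion=0.0
    )


@pytest.fixture(scope="session")
def season_weather():
    """141-day stochastic weather under the default climate profile."""
    return generate_weather(LIMA_2017_PROFILE, DEFAULT_PLANTING_DATE, 141, seed=11)


@pytest.fixture(scope="session")
def noisy_trial():
    """Full-size synthetic trial under the default (noisy) conditions."""
    return generate_trial(TrialConfig(seed=1))


@pytest.fixture(scope="session")
def noisy_results(noisy_trial):
    return analyze_trial(noisy_trial, PipelineConfig(seed=1))


@pytest.fixture(scope="session")
def noiseless_trial():
    """Full-size trial with every noise source off (recovery checks)."""
    return generate_trial(TrialConfig(seed=2).noiseless())


@pytest.fixture(scope="session")
def noiseless_results(noiseless_trial):
    return analyze_trial(noiseless_trial, PipelineConfig(seed=2))


@pytest.fixture(scope="session")
def small_trial():
    """A 2-block, 8+2-accession noiseless trial for cheap end-to-end tests."""
    cfg = TrialConfig(
        n_new=8, n_checks=2, n_blocks=2, new_per_block=4, seed=5
    ).noiseless()
    return generate_trial(cfg)
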