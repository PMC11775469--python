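import pytest
from hypothesis import settings

from fluxpam import NoiseLevels, PipelineConfig, Scenario, run_pipeline, simulate_campaign

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def zero_sink_scenario():
    """3-day noise-free campaign with no respiration or electron diversions."""
    return Scenario(
        resp_fraction=0.0,
        photoresp_fraction=0.0,
        alt_sink_fraction=0.0,
        noise=NoiseLevels.zero(),
        seed=11,
    )


@pytest.fixture(scope="session")
def zero_sink_campaign(zero_sink_scenario):
    return simulate_campaign(zero_sink_scenario)


@pytest.fixture(scope="session")
def zero_sink_result(zero_sink_campaign):
    return run_pipeline(zero_sink_campaign.chamber, zero_sink_campaign.pam, PipelineConfig())


@pytest.fixture(scope="session")
def default_noise_free_campaign():
    """3-day noise-free campaign with the default (realistic) physiology."""
    return simulate_campaign(Scenario(noise=NoiseLevels.zero(), seed=7))


@pytest.fixture(scope="session")
def default_noise_free_result(default_noise_free_campaign):
    c = default_noise_free_campaign
    return run_pipeline(c.chamber, c.pam, PipelineConfig())
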