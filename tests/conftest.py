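import numpy as np
import pytest

from procmon.synthetic import CampaignConfig, generate_campaign


@pytest.fixture(scope="session")
def default_config() -> CampaignConfig:
    return CampaignConfig(seed=11)


@pytest.fixture(scope="session")
def campaign(default_config):
    """One default campaign shared by read-only tests."""
    return generate_campaign(default_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
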