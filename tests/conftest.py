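import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

from melt2d import load_bundled_panel
from melt2d.simulate import SimulationParams, fixture_cohort


@pytest.fixture(scope="session")
def panel():
    return load_bundled_panel()


@pytest.fixture(scope="session")
def fixture116(panel):
    return fixture_cohort(panel)


@pytest.fixture()
def noiseless():
    return SimulationParams(noise_sd=0.0)
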