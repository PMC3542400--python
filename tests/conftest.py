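import pytest
from hypothesis import settings

from masafort import GeneratorConfig, generate_survey

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from masafort.fortification import FortificationScenario


@pytest.fixture(scope="session")
def small_survey():
    """An 800-person synthetic survey shared across read-only tests."""
    return generate_survey(GeneratorConfig(n_persons=800, seed=3))


@pytest.fixture(scope="session")
def scenario():
    """Default fortification scenario (140 µg/100 g, packaged food list)."""
    return FortificationScenario()
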