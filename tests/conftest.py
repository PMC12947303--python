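import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("det")

from stimglia import GeneratorConfig, StimulationParadigm, generate_session


@pytest.fixture(scope="session")
def paradigm():
    return StimulationParadigm()


@pytest.fixture(scope="session")
def small_session():
    """A compact but complete synthetic session shared across suites."""
    cfg = GeneratorConfig(seed=42, n_neurons=80, n_microglia=12)
    return generate_session(cfg)
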