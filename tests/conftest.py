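import pytest
from hypothesis import HealthCheck, settings

from crispec.simulate import SimulationConfig, make_fixture

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_bundle():
    """A reduced fixture (2 true / 2 SSR / 4 clean, 150x) for unit tests."""
    cfg = SimulationConfig(genome_length=8000, n_reads=150, seed=11)
    return make_fixture(cfg, n_true_offtargets=2, n_ssr_noise_sites=2, n_clean_sites=4)


@pytest.fixture(scope="session")
def default_bundle():
    """The default study fixture: 3 true / 5 SSR-noise / 20 clean at 300x."""
    return make_fixture(SimulationConfig())
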