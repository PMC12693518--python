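import pytest

from berpatch import SimulationConfig, ladder_for, make_probe


@pytest.fixture(scope="session")
def g_config():
    return SimulationConfig(seed=1, label_side="downstream_G")


@pytest.fixture(scope="session")
def a_config():
    return SimulationConfig(seed=1, label_side="upstream_A")


@pytest.fixture(scope="session")
def g_probe(g_config):
    """Default patch-size probe: U in the NdeI site, six heavy G downstream."""
    return make_probe(g_config)


@pytest.fixture(scope="session")
def a_probe(a_config):
    """Default 5'-excision probe: four heavy A upstream of the lesion."""
    return make_probe(a_config)


@pytest.fixture(scope="session")
def g_ladder(g_probe, g_config):
    return ladder_for(g_probe, g_config)


@pytest.fixture(scope="session")
def a_ladder(a_probe, a_config):
    return ladder_for(a_probe, a_config)
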