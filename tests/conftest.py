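import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from perturbxtal.synthetic import SyntheticConfig, build_toy_crystal, simulate_map

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy():
    """The default synthetic crystal: 15-residue helix + 20 waters, P2₁2₁2₁."""
    return build_toy_crystal()


@pytest.fixture(scope="session")
def toy_map(toy):
    """Noiseless Gaussian-atom map of the default toy crystal (0.3 Å grid)."""
    return simulate_map(toy, grid=0.3)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240112)
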