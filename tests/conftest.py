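import pytest

from famsynt.domains import build_pssm, load_seed_alignment
from famsynt.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def pssms():
    return {name: build_pssm(load_seed_alignment(name), name) for name in ("QLQ", "WRC")}


@pytest.fixture(scope="session")
def small_sim():
    """One default three-species simulation shared across read-only tests."""
    return simulate(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def one_species_sim():
    return simulate(SimulationConfig(seed=12, n_species=1))
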