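import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from dscircuit.biophysics import BiophysicsConfig, build_cell
from dscircuit.circuit_geometry import (
    SOMA,
    TERMINAL,
    ArborConfig,
    Compartment,
    Morphology,
    generate_arbor,
    place_synapses,
)

NO_NOISE = BiophysicsConfig(noise_sd_ma_cm2=0.0)
PASSIVE = BiophysicsConfig(
    channel_densities={r: (0.0, 0.0, 0.0)
                       for r in ("soma", "primary_dendrite",
                                 "terminal_dendrite")},
    noise_sd_ma_cm2=0.0)


@pytest.fixture(scope="session")
def arbor():
    return generate_arbor(ArborConfig(), seed=1)


@pytest.fixture(scope="session")
def sites(arbor):
    return place_synapses(arbor, 10.0, seed=1)


@pytest.fixture(scope="session")
def cell(arbor, sites):
    """Default model cell with noise disabled (deterministic tests)."""
    return build_cell(arbor, sites, NO_NOISE)


@pytest.fixture(scope="session")
def soma_only():
    """A single spherical soma, 15 µm diameter."""
    return Morphology((Compartment(0, -1, (0.0, 0.0), 15.0, 0.0, SOMA),), 150.0)


@pytest.fixture(scope="session")
def passive_soma_cell(soma_only):
    return build_cell(soma_only, [], PASSIVE)


@pytest.fixture()
def one_branch_morphology():
    """Soma plus a single 100 µm terminal branch along +x."""
    return Morphology((
        Compartment(0, -1, (0.0, 0.0), 15.0, 0.0, SOMA),
        Compartment(1, 0, (107.5, 0.0), 0.7, 100.0, TERMINAL),
    ), 150.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
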