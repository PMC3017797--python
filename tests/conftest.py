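import numpy as np
import pytest

from rgacluster.synthetic_data import SimulationConfig, simulate_pair


@pytest.fixture(scope="session")
def default_pair():
    """One default-condition simulated haplotype pair, shared across tests."""
    return simulate_pair(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def clean_pair():
    """A pair without recombination or retroelement events: allele pairing
    and clade truth are exact."""
    cfg = SimulationConfig(seed=5, intragenic_event=False, retro_events=[])
    return simulate_pair(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_dna(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=n))


@pytest.fixture()
def make_dna(rng):
    def _make(n):
        return random_dna(rng, n)

    return _make
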