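import numpy as np
import pytest

from radhap import geometry
from radhap.simulate import SimConfig, simulate_locus


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_locus_seq(rng) -> str:
    """Random 696-bp locus sequence with the PstI motif in place."""
    seq = rng.choice(list("ACGT"), size=geometry.LOCUS_LEN)
    seq[geometry.MOTIF_START : geometry.MOTIF_START + geometry.MOTIF_LEN] = list(
        geometry.MOTIF
    )
    return "".join(seq)


@pytest.fixture
def locus_seq(rng):
    return random_locus_seq(rng)


@pytest.fixture(scope="session")
def sim_loci():
    """A small bank of simulated loci shared across tests (read-only)."""
    cfg = SimConfig(n_loci=30, seed=4242, frac_divergent=0.2)
    return cfg, [simulate_locus(cfg, i, 1000 + 10_000 * i) for i in range(30)]
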