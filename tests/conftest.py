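import numpy as np
import pytest

import crossmotif as cm
from crossmotif._seq import AMINO_ACIDS


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, length))


@pytest.fixture(scope="session")
def small_family() -> cm.SequenceFamily:
    """One simulated family of 20 diverged homologues, no planted motifs."""
    cfg = cm.SimConfig(
        n_families=1,
        seqs_per_family=20,
        ancestor_length=120,
        substitution_rate=0.2,
        indel_rate=0.02,
        seed=3,
    )
    return cm.simulate_families(cfg)[0]


@pytest.fixture(scope="session")
def three_families() -> list[cm.SequenceFamily]:
    """Three mutually unrelated families of 30 homologues each."""
    cfg = cm.SimConfig(
        n_families=3,
        seqs_per_family=30,
        ancestor_length=150,
        substitution_rate=0.3,
        indel_rate=0.0,
        seed=42,
    )
    return cm.simulate_families(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
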