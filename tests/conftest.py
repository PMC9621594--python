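import numpy as np
import pytest

from cgdnafold import (
    chain_from_sequence,
    default_params,
    ideal_bform_duplex,
    ideal_bform_strand,
    ideal_hairpin,
)


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def duplex_gcgc():
    return ideal_bform_duplex("GCGC")


@pytest.fixture(scope="session")
def hairpin13():
    """Ideal-stem GCGC(T)5GCGC hairpin fixture."""
    s = ideal_hairpin("GCGCTTTTTGCGC", 4)
    s.ion_condition = (1.0, 0.0)
    return s


@pytest.fixture()
def coil13():
    return chain_from_sequence("GCGCTTTTTGCGC", seed=7, ion_condition=(1.0, 0.0))


@pytest.fixture(scope="session")
def strand_extended():
    """A fully extended single strand: no pairing geometry anywhere."""
    s = ideal_bform_strand("GCGCGCGC")
    pos = s.positions.copy()
    # stretch along z so every N-N distance exceeds the pairing window
    pos[:, 2] *= 6.0
    s.positions = pos
    return s


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
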