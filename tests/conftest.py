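import numpy as np
import pytest

from trimp3.simulate import make_trna_library


@pytest.fixture(scope="session")
def trna_library():
    """Deterministic synthetic tRNA library shared across tests."""
    return make_trna_library(1234)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
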