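import numpy as np
import pytest

from covadduct.digest import ProteinSequence
from covadduct.synthetic import shp2_like_sequence


@pytest.fixture(scope="session")
def shp2_standin() -> ProteinSequence:
    return shp2_like_sequence()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: np.random.Generator, length: int, pid: str = "P1") -> ProteinSequence:
    residues = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    return ProteinSequence(id=pid, residues=residues)
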