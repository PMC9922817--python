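import numpy as np
import pytest
from importlib import resources

from mitopulse.proteins import ProteinRecord, read_fasta


@pytest.fixture(scope="session")
def nd4l() -> ProteinRecord:
    """Canonical human MT-ND4L (UniProt P03901) from the packaged FASTA."""
    path = resources.files("mitopulse.data") / "mt_nd4l.fasta"
    with resources.as_file(path) as p:
        return read_fasta(p)[0]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    """Random sequence over the 20 canonical residues (uniform)."""
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
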