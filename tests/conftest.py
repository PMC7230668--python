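import numpy as np
import pytest

from krillsurvey.seq_io import SeqRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(AA20[i] for i in rng.integers(0, 20, size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(20200331)


@pytest.fixture
def small_reads():
    return [
        SeqRecord(id="r1", seq="ACGTACGTAC", quals=[40] * 10),
        SeqRecord(id="r2", seq="TTTTGGGGCC", quals=[40] * 10),
    ]
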