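import numpy as np
import pytest

from nonbscan.seqio import Contig, GenomeAssembly


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_contig(rng):
    def make(length: int = 500, gc: float = 0.5, name: str = "rnd") -> Contig:
        p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        seq = "".join(rng.choice(list("ACGT"), size=length, p=p))
        return Contig(name, seq)

    return make


@pytest.fixture
def tiny_assembly():
    return GenomeAssembly(
        [
            Contig("cenA", "GCGCGTTTCGCGC" + "AT" * 20),
            Contig("bg1", "ACGT" * 300),
            Contig("bg2", "GATTACA" * 150),
        ],
        centromere_ids={"cenA"},
    )
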