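import numpy as np
import pytest

from lathework import ContigRecord, GenomeSpec, make_genome


@pytest.fixture
def small_genome():
    contig, _truth = make_genome(GenomeSpec(length=20_000, seed=7))
    return contig


def random_contig(length: int, seed: int, name: str = "c") -> ContigRecord:
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return ContigRecord(id=f"{name}{seed}", seq=seq)
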