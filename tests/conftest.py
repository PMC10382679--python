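import numpy as np
import pytest

from repairscreen.genes import GeneModel
from repairscreen.fastq import Read, constant_quality


@pytest.fixture
def tiny_gene() -> GeneModel:
    """120-bp gene, TSS at position 21, fragment spanning 11..110."""
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=120))
    return GeneModel(
        name="tiny",
        sequence=seq,
        tss=21,
        fragment_bounds=(11, 110),
        nucleosome_intervals=((5, 40, "core"), (41, 60, "linker")),
    )


def make_read(seq: str, rid: str = "r", q: int = 40) -> Read:
    return Read(rid, seq, constant_quality(len(seq), q))
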