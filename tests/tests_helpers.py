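"""Shared helpers for the test suite."""

import pandas as pd

from repairscreen.screen_reads import AMINO_ACIDS, CodonCountMatrix


def matrix_with_covered(n_covered: int, count: int = 3) -> CodonCountMatrix:
    """A codon count matrix with exactly ``n_covered`` detected
    (position, amino-acid) variants over the 2-171 mutable range."""
    rows = []
    i = 0
    for pos in range(2, 172):
        for aa in AMINO_ACIDS:
            if i >= n_covered:
                break
            rows.append((pos, "NNN", aa, "UV_r1", count))
            i += 1
    counts = pd.DataFrame(rows, columns=["position", "codon", "aa", "sample",
                                         "count"])
    return CodonCountMatrix(counts=counts, depths=pd.Series({"UV_r1": 10_000}))
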