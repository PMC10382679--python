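"""Minimal FASTQ records and 4-line Phred+33 I/O.

Reading goes through Biopython's parser; writing is plain 4-line records with
a constant (configurable) quality, which is all the simulator emits.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Iterator

from Bio import SeqIO


@dataclass(frozen=True)
class Read:
    id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")


def read_fastq(path: str | os.PathLike) -> Iterator[Read]:
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        yield Read(rec.description, str(rec.seq), qual)


def write_fastq(path: str | os.PathLike, reads: Iterable[Read]) -> int:
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")
            n += 1
    return n


def constant_quality(length: int, q: int = 40) -> str:
    return chr(q + 33) * length
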