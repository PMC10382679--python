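"""Gene models for restriction-released fragments analysed at single-lesion resolution.

A :class:`GeneModel` carries one gene's top-strand (coding) sequence together with
the coordinate frame used throughout the repair branch: positions are reported
relative to the major transcription start site (TSS), where +1 is the first
transcribed base and there is no position 0 (the base immediately upstream of the
TSS is -1).  The transcribed strand (TS) is therefore the bottom strand and the
nontranscribed strand (NTS) the top strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Sequence, Tuple

import numpy as np

_DNA = set("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: dinucleotides at which cyclobutane pyrimidine dimers form
PYRIMIDINES = frozenset("CT")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """One gene's sequence and annotations in the TSS-anchored frame.

    Parameters
    ----------
    name
        Gene identifier.
    sequence
        Top-strand (coding) DNA sequence; transcription runs left to right,
        so the bottom strand is the transcribed strand (TS).
    tss
        1-based top-strand position of the major TSS (+1 of the gene frame).
    fragment_bounds
        Closed 1-based interval ``(start, end)`` on the top strand delimiting
        the restriction-released fragment.
    nucleosome_intervals
        ``(start, end, label)`` triples in TSS-relative coordinates with label
        ``"core"`` or ``"linker"``; intervals must not overlap.
    strand_labels
        Which physical strand is TS / NTS. Default matches a gene whose coding
        strand is the top strand.
    """

    name: str
    sequence: str
    tss: int
    fragment_bounds: Tuple[int, int]
    nucleosome_intervals: Tuple[Tuple[int, int, str], ...] = ()
    strand_labels: Mapping[str, str] = field(
        default_factory=lambda: MappingProxyType({"TS": "bottom", "NTS": "top"})
    )

    def __post_init__(self) -> None:
        if set(self.sequence) - _DNA:
            bad = sorted(set(self.sequence) - _DNA)
            raise ValueError(f"{self.name}: non-ACGT characters in sequence: {bad}")
        lo, hi = self.fragment_bounds
        if not (1 <= lo <= hi <= len(self.sequence)):
            raise ValueError(f"{self.name}: fragment_bounds {self.fragment_bounds} "
                             f"outside sequence of length {len(self.sequence)}")
        if not (lo <= self.tss <= hi):
            raise ValueError(f"{self.name}: TSS {self.tss} outside fragment bounds")
        ivals = sorted(self.nucleosome_intervals)
        for (a0, a1, lab) in ivals:
            if a0 > a1:
                raise ValueError(f"{self.name}: inverted nucleosome interval {(a0, a1)}")
            if lab not in ("core", "linker"):
                raise ValueError(f"{self.name}: nucleosome label must be core|linker, got {lab!r}")
        for (a, b) in zip(ivals, ivals[1:]):
            if b[0] <= a[1]:
                raise ValueError(f"{self.name}: overlapping nucleosome intervals {a} and {b}")
        if set(self.strand_labels) != {"TS", "NTS"} or \
                set(self.strand_labels.values()) != {"top", "bottom"}:
            raise ValueError(f"{self.name}: strand_labels must map TS/NTS onto top/bottom")
        object.__setattr__(self, "nucleosome_intervals", tuple(ivals))

    # -- coordinate frame ---------------------------------------------------
    def to_relative(self, pos: int) -> int:
        """1-based top-strand position -> TSS-relative coordinate (no 0)."""
        return pos - self.tss + 1 if pos >= self.tss else pos - self.tss

    def from_relative(self, rel: int) -> int:
        """TSS-relative coordinate -> 1-based top-strand position."""
        if rel == 0:
            raise ValueError("TSS-relative coordinate 0 does not exist")
        return rel + self.tss - 1 if rel > 0 else rel + self.tss

    def region_at(self, rel: int) -> str:
        """Nucleosome region (core | linker | other) containing a TSS-relative site."""
        for (a, b, lab) in self.nucleosome_intervals:
            if a <= rel <= b:
                return lab
        return "other"

    @property
    def fragment_sequence(self) -> str:
        lo, hi = self.fragment_bounds
        return self.sequence[lo - 1:hi]


def _random_gene(name: str, length: int, tss: int, bounds: Tuple[int, int],
                 rng: np.random.Generator) -> GeneModel:
    seq = "".join(rng.choice(list("ACGT"), size=length))
    # canonical in-gene chromatin layout: +1 nucleosome shortly after the TSS,
    # then alternating 147-bp cores and 50-bp linkers
    ivals = []
    start = 11
    for i in range(4):
        ivals.append((start, start + 146, "core"))
        start += 147
        ivals.append((start, start + 49, "linker"))
        start += 50
    return GeneModel(name=name, sequence=seq, tss=tss, fragment_bounds=bounds,
                     nucleosome_intervals=tuple(ivals))


def demo_genes(seed: int = 715) -> dict[str, GeneModel]:
    """Synthetic stand-ins for the three repair reporter genes.

    The real AGP2, RPB2 and YEF3 fragments are not distributed with the
    package; these are random sequences with the same coordinate layout
    (TSS inside a ~1 kb restriction fragment, alternating nucleosome
    cores/linkers downstream of the TSS).
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    genes = {}
    for name, child in zip(("AGP2", "RPB2", "YEF3"), ss):
        rng = np.random.default_rng(child)
        genes[name] = _random_gene(name, length=1150, tss=180, bounds=(61, 1100), rng=rng)
    return genes


def write_gene_files(genes: Mapping[str, "GeneModel"], fasta_path, annot_path) -> None:
    """Write reference FASTA plus the sidecar TSV of TSS / fragment /
    nucleosome annotations (the on-disk form of a set of GeneModels)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(g.sequence), id=g.name, description="") for g in genes.values()]
    seqio_write(recs, str(fasta_path), "fasta")
    with open(annot_path, "w") as fh:
        fh.write("gene\ttss\tfrag_start\tfrag_end\tts_strand\tnucleosomes\n")
        for g in genes.values():
            nuc = ";".join(f"{a}..{b}:{lab}" for a, b, lab in g.nucleosome_intervals)
            fh.write(f"{g.name}\t{g.tss}\t{g.fragment_bounds[0]}\t"
                     f"{g.fragment_bounds[1]}\t{g.strand_labels['TS']}\t{nuc}\n")


def load_gene_models(fasta_path, annot_path) -> dict[str, "GeneModel"]:
    """Inverse of :func:`write_gene_files`."""
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    genes: dict[str, GeneModel] = {}
    with open(annot_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            nucs = []
            if row.get("nucleosomes"):
                for part in row["nucleosomes"].split(";"):
                    span, lab = part.split(":")
                    a, b = span.split("..")
                    nucs.append((int(a), int(b), lab))
            ts = row.get("ts_strand", "bottom")
            genes[row["gene"]] = GeneModel(
                name=row["gene"], sequence=seqs[row["gene"]], tss=int(row["tss"]),
                fragment_bounds=(int(row["frag_start"]), int(row["frag_end"])),
                nucleosome_intervals=tuple(nucs),
                strand_labels={"TS": ts, "NTS": "top" if ts == "bottom" else "bottom"},
            )
    return genes


def dipyrimidine_offsets(seq: str) -> np.ndarray:
    """0-based offsets of the 5' base of each dipyrimidine in ``seq``."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    pyr = (arr == ord("C")) | (arr == ord("T"))
    return np.nonzero(pyr[:-1] & pyr[1:])[0]


def sequences_to_matrix(seqs: Sequence[str]) -> np.ndarray:
    """Stack equal-length sequences into a (n, L) uint8 matrix."""
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    L = len(seqs[0])
    buf = "".join(seqs).encode()
    mat = np.frombuffer(buf, dtype=np.uint8)
    if mat.size != len(seqs) * L:
        raise ValueError("sequences have unequal lengths")
    return mat.reshape(len(seqs), L).copy()


def matrix_to_sequences(mat: np.ndarray) -> list[str]:
    return [row.tobytes().decode() for row in mat]
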