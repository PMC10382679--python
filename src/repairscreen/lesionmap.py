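"""Strand-specific mapping of lesion-adjoining fragment reads.

The assay converts each cyclobutane pyrimidine dimer (CPD) into a strand
incision immediately 5' of the lesion; the captured fragment therefore runs
from the restriction-fragment 5' boundary of its strand to the base just 5' of
the dimer, and the 3'-terminal base of a sequencing read (the adapter-ligation
junction) reports the lesion position.  Reads are placed by anchored prefix
search against short per-strand references; lesions are assigned to the
dinucleotide immediately 3' of the junction and rejected unless it is a
pyrimidine-pyrimidine pair.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genes import GeneModel, PYRIMIDINES, dipyrimidine_offsets, revcomp


@dataclass(frozen=True)
class StrandReference:
    """One strand of a restriction fragment, 5'->3', with its coordinate map."""

    gene: str
    strand: str                 # "TS" | "NTS"
    sequence: str
    coords: np.ndarray          # TSS-relative gene coordinate of each offset

    def coord(self, offset: int) -> int:
        return int(self.coords[offset])

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def dipyrimidine_sites(self) -> np.ndarray:
        """Offsets of the 5' base of every dipyrimidine on this strand."""
        return dipyrimidine_offsets(self.sequence)


def build_strand_references(gene: GeneModel) -> dict[str, StrandReference]:
    """TS and NTS references spanning the restriction fragment.

    Offsets run 5'->3' along each strand; the coordinate map converts a
    reference offset to the TSS-relative coordinate of that base (top-strand
    frame, +1 at the TSS, no 0).
    """
    lo, hi = gene.fragment_bounds
    top = gene.fragment_sequence
    top_positions = np.arange(lo, hi + 1)
    rel = np.where(top_positions >= gene.tss,
                   top_positions - gene.tss + 1,
                   top_positions - gene.tss)
    refs_by_phys = {
        "top": StrandReference(gene.name, "", top, rel.astype(np.int64)),
        "bottom": StrandReference(gene.name, "", revcomp(top), rel[::-1].astype(np.int64).copy()),
    }
    out = {}
    for label, phys in gene.strand_labels.items():
        r = refs_by_phys[phys]
        out[label] = StrandReference(gene.name, label, r.sequence, r.coords)
    return out


@dataclass(frozen=True)
class MappedRead:
    read_id: str
    strand: str
    junction_offset: int    # 0-based reference offset of the read's 3'-terminal base
    junction_coord: int     # TSS-relative coordinate of that base


def _prefix_mismatches(read: str, ref: str, limit: int) -> int | None:
    """Hamming distance of ``read`` vs the reference prefix, or None if > limit."""
    if len(read) > len(ref):
        return None
    if ref.startswith(read):
        return 0
    mm = 0
    for a, b in zip(read, ref):
        if a != b:
            mm += 1
            if mm > limit:
                return None
    return mm


def _capture_label(read_id: str) -> str | None:
    for tok in read_id.split():
        if tok.startswith("cap="):
            return tok[4:]
    return None


def map_lesion_reads(
    reads: Iterable,
    refs: Mapping[str, StrandReference],
    min_len: int = 10,
    max_mismatch: int = 2,
) -> tuple[list[MappedRead], list[tuple[str, str]]]:
    """Place reads as anchored prefixes of the strand references.

    Returns accepted placements (strand + 3'-junction coordinate) and a log of
    ``(read_id, reason)`` for unmapped reads.  Reads matching both strands are
    resolved by a ``cap=TS|NTS`` token in the read id (the strand-specific
    capture label) when present, otherwise dropped as ambiguous.  Identical
    sequences map identically, so placements are memoized per sequence;
    mapping is deterministic and independent of input order.
    """
    mapped: list[MappedRead] = []
    unmapped: list[tuple[str, str]] = []
    cache: dict[str, tuple[str, ...]] = {}

    def place(seq: str) -> tuple[str, ...]:
        hits = []
        for strand in ("TS", "NTS"):
            mm = _prefix_mismatches(seq, refs[strand].sequence, max_mismatch)
            if mm is not None:
                hits.append(strand)
        return tuple(hits)

    for r in reads:
        rid, seq = (r.id, r.seq) if hasattr(r, "seq") else r
        if len(seq) < min_len:
            unmapped.append((rid, "short"))
            continue
        hits = cache.get(seq)
        if hits is None:
            hits = place(seq)
            cache[seq] = hits
        if not hits:
            unmapped.append((rid, "unmapped"))
            continue
        if len(hits) == 2:
            cap = _capture_label(rid)
            if cap in hits:
                strand = cap
            else:
                unmapped.append((rid, "ambiguous"))
                continue
        else:
            strand = hits[0]
        off = len(seq) - 1
        mapped.append(MappedRead(rid, strand, off, refs[strand].coord(off)))
    return mapped, unmapped


@dataclass(frozen=True)
class LesionCall:
    read_id: str
    strand: str
    site_offset: int    # offset of the 5' base of the lesion dipyrimidine
    site_coord: int     # TSS-relative coordinate of that base


def call_lesion_site(
    junction: MappedRead, refs: Mapping[str, StrandReference]
) -> LesionCall | tuple[str, str]:
    """Assign the lesion to the dinucleotide immediately 3' of the junction.

    Site key is the coordinate of the dipyrimidine's 5' base on the same
    strand.  Returns a :class:`LesionCall`, or ``(read_id, reason)`` when the
    junction sits at the fragment 3' end ("edge" - full-length restriction
    fragments with no lesion) or the downstream dinucleotide is not a
    pyrimidine pair ("non_dipyrimidine").
    """
    ref = refs[junction.strand]
    j = junction.junction_offset + 1
    if j + 1 >= len(ref):
        return (junction.read_id, "edge")
    dinuc = ref.sequence[j:j + 2]
    if dinuc[0] in PYRIMIDINES and dinuc[1] in PYRIMIDINES:
        return LesionCall(junction.read_id, junction.strand, j, ref.coord(j))
    return (junction.read_id, "non_dipyrimidine")


@dataclass
class LesionCountTable:
    """Per-sample, per-strand lesion counts for one gene.

    ``counts`` is a site x sample table keyed by the TSS-relative coordinate of
    the 5' base of each dipyrimidine; ``depth`` is the total number of reads
    mapped to this strand per sample (including mapped reads rejected at
    lesion calling, e.g. full-length fragments) - the stable normalization
    anchor for between-sample comparisons.
    """

    gene: str
    strand: str
    counts: pd.DataFrame
    depth: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative lesion counts")
        self.counts = self.counts.sort_index()


def count_lesions(
    calls_per_sample: Mapping[str, Sequence[LesionCall]],
    depth_per_sample: Mapping[str, int],
    gene: str,
    strand: str,
) -> LesionCountTable:
    """Histogram accepted lesion calls per sample into a :class:`LesionCountTable`."""
    samples = list(calls_per_sample)
    counters = {s: Counter(c.site_coord for c in calls_per_sample[s]
                           if c.strand == strand) for s in samples}
    sites = sorted(set().union(*[set(c) for c in counters.values()]) or set())
    counts = pd.DataFrame(
        {s: [counters[s].get(site, 0) for site in sites] for s in samples},
        index=pd.Index(sites, name="site"), dtype=np.int64,
    )
    depth = pd.Series({s: int(depth_per_sample[s]) for s in samples}, name="depth")
    return LesionCountTable(gene=gene, strand=strand, counts=counts, depth=depth)


def map_and_count(
    reads_per_sample: Mapping[str, Sequence],
    refs: Mapping[str, StrandReference],
    gene: str,
    min_len: int = 10,
    max_mismatch: int = 2,
) -> tuple[dict[str, LesionCountTable], pd.DataFrame]:
    """Full mapping stage: reads -> per-strand LesionCountTables + a reject log."""
    calls: dict[str, dict[str, list[LesionCall]]] = {"TS": {}, "NTS": {}}
    depths: dict[str, dict[str, int]] = {"TS": {}, "NTS": {}}
    log_rows = []
    for sample, reads in reads_per_sample.items():
        mapped, unmapped = map_lesion_reads(reads, refs, min_len, max_mismatch)
        for rid, reason in unmapped:
            log_rows.append((sample, rid, reason))
        per_strand: dict[str, list[LesionCall]] = {"TS": [], "NTS": []}
        n_mapped = {"TS": 0, "NTS": 0}
        for m in mapped:
            n_mapped[m.strand] += 1
            res = call_lesion_site(m, refs)
            if isinstance(res, LesionCall):
                per_strand[m.strand].append(res)
            else:
                log_rows.append((sample, res[0], res[1]))
        for strand in ("TS", "NTS"):
            calls[strand][sample] = per_strand[strand]
            depths[strand][sample] = n_mapped[strand]
    tables = {
        strand: count_lesions(calls[strand], depths[strand], gene, strand)
        for strand in ("TS", "NTS")
    }
    log = pd.DataFrame(log_rows, columns=["sample", "read_id", "reason"])
    return tables, log
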