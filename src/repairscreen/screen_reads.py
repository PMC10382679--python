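"""Paired-end amplicon processing for the codon-variant screen.

``merge_read_pairs`` joins mates over their best-scoring overlap,
``call_codon_variants`` reports every mutated codon of a merged read against
the reference ORF (frame anchored by exact 12-nt flanks), and
``count_codon_variants`` accumulates calls into a :class:`CodonCountMatrix`.

Each operation has a simple per-read reference implementation (the contract)
and the pipeline uses vectorized bulk equivalents operating on uint8 base
matrices; the test suite asserts the two routes agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fastq import Read
from .genes import matrix_to_sequences, revcomp, sequences_to_matrix
from .simulate import CODON_TABLE, PairedReadSet

AMINO_ACIDS = tuple(sorted(set(CODON_TABLE.values()) - {"*"}))  # the 20 standard aa


# ---------------------------------------------------------------------------
# read-pair merging
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MergedRead:
    id: str
    seq: str
    qual: str
    overlap: int
    mismatches: int


def _hamming(a: str, b: str) -> int:
    if a == b:
        return 0
    x = np.frombuffer(a.encode(), dtype=np.uint8)
    y = np.frombuffer(b.encode(), dtype=np.uint8)
    n = min(x.size, y.size)
    return int((x[:n] != y[:n]).sum())


def merge_pair(
    r1: Read,
    r2: Read,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
) -> MergedRead | tuple[str, str]:
    """Join one mate pair (mates oriented toward each other).

    The overlap is the offset maximizing matches - mismatches over all
    overlaps >= ``min_overlap`` (ties broken toward the longer overlap);
    overlap mismatches are resolved toward the higher base quality (equal
    quality: mate 1).  Returns ``(read_id, reason)`` on rejection.
    """
    if len(r1.seq) == 0 or len(r2.seq) == 0:
        return (r1.id, "empty")
    rc2 = revcomp(r2.seq)
    q2r = r2.qual[::-1]
    best: tuple[int, int, int] | None = None  # (score, overlap, mismatches)
    max_ov = min(len(r1.seq), len(rc2))
    a = np.frombuffer(r1.seq.encode(), dtype=np.uint8)
    b = np.frombuffer(rc2.encode(), dtype=np.uint8)
    for ov in range(max_ov, min_overlap - 1, -1):
        mm = int((a[len(a) - ov:] != b[:ov]).sum())
        score = ov - 2 * mm
        if best is None or score > best[0]:
            best = (score, ov, mm)
    if best is None:
        return (r1.id, "short_overlap")
    _, ov, mm = best
    if mm / ov > max_mismatch_frac:
        return (r1.id, "short_overlap")
    head = r1.seq[:-ov] if ov < len(r1.seq) else ""
    head_q = r1.qual[:-ov] if ov < len(r1.seq) else ""
    mid = []
    mid_q = []
    for i in range(ov):
        a, qa = r1.seq[len(r1.seq) - ov + i], r1.qual[len(r1.qual) - ov + i]
        b, qb = rc2[i], q2r[i]
        if a == b or qa >= qb:
            mid.append(a)
        else:
            mid.append(b)
        mid_q.append(max(qa, qb))
    merged = head + "".join(mid) + rc2[ov:]
    qual = head_q + "".join(mid_q) + q2r[ov:]
    return MergedRead(r1.id, merged, qual, ov, mm)


def merge_read_pairs(
    pairs: Iterable[tuple[Read, Read]],
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
) -> tuple[list[MergedRead], list[tuple[str, str]]]:
    """Merge an iterable of mate pairs; returns merged reads + rejection log."""
    merged, rejected = [], []
    for r1, r2 in pairs:
        res = merge_pair(r1, r2, min_overlap, max_mismatch_frac)
        if isinstance(res, MergedRead):
            merged.append(res)
        else:
            rejected.append(res)
    return merged, rejected


def merge_pairs_bulk(
    reads: PairedReadSet,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
) -> tuple[np.ndarray, list[str], int]:
    """Vectorized merge for constant-length, constant-quality mate matrices.

    Seeds the candidate overlap with the first 16 bases of the
    reverse-complemented mate 2 (one ``bytes.find`` per read), verifies the
    full overlap per offset group, and routes reads the fast path cannot place
    through :func:`merge_pair`.  With equal qualities the overlap consensus is
    mate 1, so merging reduces to concatenation.  Returns the dominant-offset
    merged base matrix, merged sequences of any other offsets as strings, and
    the number of rejected pairs.
    """
    from .fastq import constant_quality

    r1, r2 = reads.r1, reads.r2
    n, L1 = r1.shape
    if n == 0:
        return np.empty((0, 0), dtype=np.uint8), [], 0
    rc2 = np.ascontiguousarray(r2[:, ::-1])
    rc2 = np.frombuffer(rc2.tobytes().translate(bytes.maketrans(b"ACGT", b"TGCA")),
                        dtype=np.uint8).reshape(rc2.shape)
    L2 = rc2.shape[1]
    seed_len = min(16, L2)
    r1_bytes = r1.tobytes()
    offsets = np.full(n, -1, dtype=np.int64)
    seed2_off = seed_len if 2 * seed_len <= L2 else 0
    for i in range(n):
        seed = rc2[i, :seed_len].tobytes()
        pos = r1_bytes.find(seed, i * L1, (i + 1) * L1)
        if pos < 0 and seed2_off:
            # fall back to a second seed window for reads with an error in the first
            seed = rc2[i, seed2_off:seed2_off + seed_len].tobytes()
            pos = r1_bytes.find(seed, i * L1, (i + 1) * L1)
            if pos >= 0:
                pos -= seed2_off
        if pos >= i * L1:
            offsets[i] = min(L1 - (pos - i * L1), L2)
    rejected = 0
    groups: dict[int, list[np.ndarray]] = {}
    fallback: list[int] = []
    for ov in np.unique(offsets):
        idx = np.nonzero(offsets == ov)[0]
        if ov < min_overlap:
            fallback.extend(int(i) for i in idx)
            continue
        ov = int(ov)
        mm = (r1[idx, L1 - ov:L1] != rc2[idx, :ov]).sum(axis=1)
        ok = mm / ov <= max_mismatch_frac
        fallback.extend(int(i) for i in idx[~ok])
        if ok.any():
            groups.setdefault(ov, []).append(idx[ok])
    extra: dict[int, list[str]] = {}
    q1 = constant_quality(L1, reads.quality)
    q2 = constant_quality(L2, reads.quality)
    for i in sorted(fallback):
        res = merge_pair(Read(str(i), r1[i].tobytes().decode(), q1),
                         Read(str(i), r2[i].tobytes().decode(), q2),
                         min_overlap, max_mismatch_frac)
        if isinstance(res, MergedRead):
            extra.setdefault(res.overlap, []).append(res.seq)
        else:
            rejected += 1
    sizes = {ov: sum(a.size for a in arrs) for ov, arrs in groups.items()}
    for ov, seqs in extra.items():
        sizes[ov] = sizes.get(ov, 0) + len(seqs)
    if not sizes:
        return np.empty((0, 0), dtype=np.uint8), [], rejected
    main_ov = max(sizes, key=lambda k: (sizes[k], k))
    parts = []
    if main_ov in groups:
        idx = np.concatenate(groups[main_ov])
        parts.append(np.concatenate([r1[idx], rc2[idx, main_ov:]], axis=1))
    if main_ov in extra:
        parts.append(sequences_to_matrix(extra[main_ov]))
    merged = np.concatenate(parts, axis=0) if len(parts) > 1 else parts[0]
    strays: list[str] = []
    for ov, arrs in groups.items():
        if ov == main_ov:
            continue
        for idx in arrs:
            sub = np.concatenate([r1[idx], rc2[idx, ov:]], axis=1)
            strays.extend(matrix_to_sequences(sub))
    for ov, seqs in extra.items():
        if ov != main_ov:
            strays.extend(seqs)
    return merged, strays, rejected


# ---------------------------------------------------------------------------
# codon-variant calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantCall:
    position: int
    codon: str
    aa: str
    synonymous: bool


@dataclass(frozen=True)
class OrfReference:
    """Reference ORF with the fixed flanking anchors that lock the frame."""

    orf: str
    flank5: str
    flank3: str
    mutable_codons: tuple[int, int] = (2, 171)

    def __post_init__(self) -> None:
        if len(self.orf) % 3:
            raise ValueError("ORF length must be a multiple of 3")

    def ref_codon(self, pos: int) -> str:
        return self.orf[3 * (pos - 1):3 * pos]

    def ref_aa(self, pos: int) -> str:
        return CODON_TABLE[self.ref_codon(pos)]


def call_codon_variants(
    merged_seq: str,
    reference: OrfReference,
) -> list[VariantCall] | tuple[None, str]:
    """Every codon in the mutable range whose triplet differs from reference.

    The frame is anchored by exact matches of the two 12-nt flanks; reads in
    which either anchor is missing, or whose enclosed ORF has a different
    length (indels), are rejected with a reason.  Synonymous changes are
    reported with the reference amino acid and flagged.
    """
    i = merged_seq.find(reference.flank5)
    if i < 0:
        return (None, "no_anchor_5")
    start = i + len(reference.flank5)
    j = merged_seq.find(reference.flank3, start)
    if j < 0:
        return (None, "no_anchor_3")
    orf_read = merged_seq[start:j]
    if len(orf_read) != len(reference.orf):
        return (None, "length_mismatch")
    lo, hi = reference.mutable_codons
    calls = []
    if orf_read == reference.orf:
        return calls
    for pos in range(lo, hi + 1):
        c = orf_read[3 * (pos - 1):3 * pos]
        ref_c = reference.ref_codon(pos)
        if c != ref_c:
            aa = CODON_TABLE[c]
            calls.append(VariantCall(pos, c, aa, aa == reference.ref_aa(pos)))
    return calls


def call_variants_bulk(
    merged: np.ndarray,
    reference: OrfReference,
) -> tuple[list[list[VariantCall]], int]:
    """Vectorized :func:`call_codon_variants` over a merged base matrix.

    Returns per-read call lists (empty list = read matches reference) and the
    number of anchor-rejected reads.  Anchors are located on the first read
    and verified column-wise for the rest; reads failing the fast-path check
    are re-examined with the per-read routine.
    """
    n = merged.shape[0]
    if n == 0:
        return [], 0
    f5 = np.frombuffer(reference.flank5.encode(), dtype=np.uint8)
    f3 = np.frombuffer(reference.flank3.encode(), dtype=np.uint8)
    ref = np.frombuffer(reference.orf.encode(), dtype=np.uint8)
    first = merged[0].tobytes().decode()
    i = first.find(reference.flank5)
    anchored = None
    if i >= 0:
        start = i + len(reference.flank5)
        end = start + len(reference.orf)
        if end + len(reference.flank3) <= merged.shape[1]:
            ok5 = (merged[:, i:start] == f5).all(axis=1)
            ok3 = (merged[:, end:end + len(reference.flank3)] == f3).all(axis=1)
            anchored = ok5 & ok3
    rejected = 0
    calls: list[list[VariantCall] | None] = [None] * n
    if anchored is not None:
        idx = np.nonzero(anchored)[0]
        orfs = merged[idx, start:end]
        diff = orfs != ref
        for k in idx:
            calls[k] = []
        lo, hi = reference.mutable_codons
        rows, cols = np.nonzero(diff)
        if rows.size:
            cpos = cols // 3 + 1
            mult = len(reference.orf) // 3 + 2
            pair = np.unique(rows.astype(np.int64) * mult + cpos)
            prow = pair // mult
            ppos = (pair % mult).astype(np.int64)
            in_range = (ppos >= lo) & (ppos <= hi)
            prow, ppos = prow[in_range], ppos[in_range]
            base = 3 * (ppos - 1)
            triplets = np.ascontiguousarray(
                orfs[prow[:, None], base[:, None] + np.arange(3)])
            codons = triplets.view("S3").ravel()
            uniq, inv = np.unique(codons, return_inverse=True)
            uniq_str = [c.decode() for c in uniq]
            uniq_aa = [CODON_TABLE[c] for c in uniq_str]
            for r, pos, ci in zip(prow, ppos, inv):
                aa = uniq_aa[ci]
                calls[idx[r]].append(VariantCall(
                    int(pos), uniq_str[ci], aa, aa == reference.ref_aa(int(pos))))
        todo = np.nonzero(~anchored)[0]
    else:
        todo = np.arange(n)
    for k in todo:
        res = call_codon_variants(merged[k].tobytes().decode(), reference)
        if isinstance(res, tuple):
            rejected += 1
            calls[k] = None
        else:
            calls[k] = res
    out = [c for c in calls if c is not None]
    return out, rejected


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

@dataclass
class CodonCountMatrix:
    """Counts per (codon position, codon) per sample, plus per-sample depths.

    ``counts`` is a long-format frame (position, codon, aa, sample, count);
    ``by_amino_acid()`` pivots to the (position, aa) x sample matrix used by
    the enrichment statistics.  ``depths`` are total countable (merged and
    anchored) reads per sample.  ``counting_mode`` records whether every
    mutated codon of a read was counted (``marginal``) or only reads with a
    single mutated codon (``single_only``).
    """

    counts: pd.DataFrame
    depths: pd.Series
    counting_mode: str = "marginal"
    mutable_codons: tuple[int, int] = (2, 171)

    def by_amino_acid(self) -> pd.DataFrame:
        piv = self.counts.pivot_table(index=["position", "aa"], columns="sample",
                                      values="count", aggfunc="sum", fill_value=0)
        piv.columns.name = None
        return piv.reindex(columns=list(self.depths.index), fill_value=0)

    def pooled_aa_counts(self) -> pd.Series:
        return self.by_amino_acid().sum(axis=1)

    def to_tsv(self, path: str) -> None:
        self.counts.to_csv(path, sep="\t", index=False)


def count_codon_variants(
    calls_per_sample: Mapping[str, Sequence[Sequence[VariantCall]]],
    mode: str = "marginal",
    mutable_codons: tuple[int, int] = (2, 171),
) -> CodonCountMatrix:
    """Accumulate per-read variant calls into a :class:`CodonCountMatrix`.

    ``marginal`` increments every mutated codon of a read; ``single_only``
    increments only reads carrying exactly one mutated codon.  Depth per
    sample is the number of reads processed (including wild-type reads).
    """
    if mode not in ("marginal", "single_only"):
        raise ValueError(f"unknown counting mode {mode!r}")
    rows: dict[tuple[int, str, str, str], int] = {}
    depths = {}
    for sample, read_calls in calls_per_sample.items():
        depths[sample] = len(read_calls)
        for calls in read_calls:
            if mode == "single_only" and len(calls) != 1:
                continue
            for c in calls:
                key = (c.position, c.codon, c.aa, sample)
                rows[key] = rows.get(key, 0) + 1
    counts = pd.DataFrame(
        [(p, cdn, aa, s, n) for (p, cdn, aa, s), n in sorted(rows.items())],
        columns=["position", "codon", "aa", "sample", "count"],
    )
    return CodonCountMatrix(counts=counts,
                            depths=pd.Series(depths, name="depth"),
                            counting_mode=mode, mutable_codons=mutable_codons)


def screen_counts_from_readsets(
    samples: Mapping[str, PairedReadSet],
    reference: OrfReference,
    mode: str = "marginal",
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
) -> tuple[CodonCountMatrix, pd.DataFrame]:
    """Read sets -> merged reads -> variant calls -> counts (bulk fast path)."""
    calls_per_sample = {}
    log_rows = []
    for name, rs in samples.items():
        merged, strays, n_rej_merge = merge_pairs_bulk(rs, min_overlap,
                                                       max_mismatch_frac)
        calls, n_rej_anchor = call_variants_bulk(merged, reference)
        for seq in strays:
            res = call_codon_variants(seq, reference)
            if isinstance(res, tuple):
                n_rej_anchor += 1
            else:
                calls.append(res)
        calls_per_sample[name] = calls
        log_rows.append((name, len(rs), n_rej_merge, n_rej_anchor))
    log = pd.DataFrame(log_rows, columns=["sample", "pairs", "rejected_merge",
                                          "rejected_anchor"])
    return count_codon_variants(calls_per_sample, mode,
                                reference.mutable_codons), log
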