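"""Read-level simulators with known ground truth for both pipeline branches.

Two generators are provided:

* :func:`simulate_lesion_reads` emulates the lesion-adjoining-fragment assay:
  restriction fragments carry UV-induced CPDs at dipyrimidine sites, each
  lesion is converted into a strand incision, and the captured piece (fragment
  5' boundary up to the base just 5' of the lesion) is sequenced.  Repair is
  independent exponential decay per site, ``exp(-k t)``, with rates looked up
  by (gene, strand, nucleosome region, genotype); the unirradiated control
  carries only spurious background incisions.

* :func:`simulate_screen_reads` emulates a UV-selection screen over an
  error-prone-PCR codon library: the UV arm reweights variant frequencies by
  survival multipliers, paired-end amplicon reads are drawn multinomially with
  per-base substitution errors, and per-replicate batch perturbations are
  applied.

All randomness flows from a single integer seed through one
``numpy.random.Generator``.  Stream order for the lesion simulator: samples in
declared order (control first, then timepoints ascending), within each sample
the TS/NTS molecule split, then per strand the lesion multinomial followed by
the per-site background Poisson.  For the screen: the default library draw (if
any), then per replicate the composition jitter, then per arm (no-UV, UV) the
multinomial and the error positions for mate 1 and mate 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .fastq import Read, constant_quality, write_fastq
from .genes import GeneModel, revcomp, sequences_to_matrix
from .lesionmap import build_strand_references

DIPYRIMIDINES = ("TT", "TC", "CT", "CC")

#: standard genetic code, stop codons encoded as "*"
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = "*"

SENSE_CODONS = tuple(sorted(c for c in CODON_TABLE if CODON_TABLE[c] != "*"))
ALL_CODONS = tuple(sorted(CODON_TABLE))

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_ENCODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
_COMP = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGT", b"TGCA"):
    _COMP[_a] = _b


@dataclass
class GroundTruth:
    """Known truth emitted alongside simulated reads.

    ``screen`` rows: one per library variant with pre-selection frequency,
    survival multiplier, expected post/pre fold change and true molecule
    counts per sample.  ``repair`` rows: one per (strand, site, sample) with
    realized lesion/background read counts and the expected count.
    """

    screen: pd.DataFrame | None = None
    repair: pd.DataFrame | None = None
    depths: pd.DataFrame | None = None

    def to_tsv(self, path: str) -> None:
        df = self.screen if self.screen is not None else self.repair
        df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# lesion branch
# ---------------------------------------------------------------------------

@dataclass
class LesionSimConfig:
    """Study conditions for the lesion-mapping branch.

    ``uv_dose`` (J/m2) is record keeping only.  ``induction_weights`` are the
    relative CPD yields per dipyrimidine class; ``lesions_per_molecule`` is
    the expected number of initial CPDs per captured fragment molecule (at
    most one lesion is placed per molecule).  ``repair_rate`` is either a
    scalar (per hour) or a mapping ``(gene, strand, region, genotype) -> k``
    where any field may be the wildcard ``"*"``; the most specific matching
    entry wins.  ``background_rate`` is the expected spurious incision count
    per dipyrimidine site per sample (the unirradiated control contains only
    such background).
    """

    uv_dose: float = 120.0
    induction_weights: Mapping[str, float] = field(
        default_factory=lambda: {"TT": 68.0, "TC": 16.0, "CT": 13.0, "CC": 3.0})
    repair_rate: float | Mapping = 0.7
    timepoints: Sequence[float] = (0.0, 0.5, 1.0, 3.0)
    reads_per_sample: int = 200_000
    lesions_per_molecule: float = 0.2
    background_rate: float = 1.0
    min_site_offset: int = 20
    read_quality: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        for d, w in self.induction_weights.items():
            if d not in DIPYRIMIDINES:
                raise ValueError(f"induction weight for non-dipyrimidine {d!r}")
            if w < 0:
                raise ValueError("induction weights must be nonnegative")
        tps = list(self.timepoints)
        if not tps or tps[0] != 0 or tps != sorted(tps):
            raise ValueError("timepoints must be sorted and start at 0")
        if not 0 < self.lesions_per_molecule < 1:
            raise ValueError("lesions_per_molecule must be in (0, 1)")
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be positive")


def lookup_repair_rate(rates: float | Mapping, gene: str, strand: str,
                       region: str, genotype: str) -> float:
    """Resolve the repair rate for one site; wildcard '*' matches any field."""
    if isinstance(rates, (int, float)):
        if rates < 0:
            raise ValueError("repair rate must be >= 0")
        return float(rates)
    best: tuple[int, float] | None = None
    for key, k in rates.items():
        pairs = list(zip(key, (gene, strand, region, genotype)))
        if all(a == "*" or a == b for a, b in pairs):
            spec = sum(a != "*" for a, _ in pairs)
            if best is None or spec > best[0]:
                best = (spec, float(k))
    if best is None:
        raise KeyError(f"no repair rate for ({gene}, {strand}, {region}, {genotype})")
    if best[1] < 0:
        raise ValueError("repair rate must be >= 0")
    return best[1]


def sample_name(t: float) -> str:
    return f"{t:g}h"


def simulate_lesion_reads(
    gene: GeneModel,
    cfg: LesionSimConfig,
    genotype: str = "WT",
) -> tuple[dict[str, list[Read]], GroundTruth]:
    """Simulate one unirradiated control ("U") plus one read set per timepoint.

    Each molecule is a strand-specific captured fragment; with probability
    ``lesions_per_molecule`` it carries one CPD at a site drawn proportionally
    to the induction weights, surviving to time t with probability
    ``exp(-k t)``.  Damaged molecules yield the strand reference prefix ending
    immediately 5' of the lesion; undamaged ones yield the full fragment.
    Sites closer than ``min_site_offset`` to the capture boundary are not
    recovered (capture-oligo footprint).
    """
    rng = np.random.default_rng(cfg.seed)
    refs = build_strand_references(gene)

    per_strand = {}
    for strand in ("TS", "NTS"):
        ref = refs[strand]
        offs = ref.dipyrimidine_sites
        offs = offs[(offs >= cfg.min_site_offset) & (offs + 1 < len(ref))]
        if offs.size == 0:
            raise ValueError(f"{gene.name}/{strand}: no usable dipyrimidine in fragment")
        dinucs = [ref.sequence[j:j + 2] for j in offs]
        w = np.array([cfg.induction_weights.get(d, 0.0) for d in dinucs])
        if w.sum() == 0:
            raise ValueError(f"{gene.name}/{strand}: all dipyrimidine weights zero")
        what = w / w.sum()
        coords = np.array([ref.coord(int(j)) for j in offs])
        k = np.array([
            lookup_repair_rate(cfg.repair_rate, gene.name, strand,
                               gene.region_at(int(c)), genotype)
            for c in coords
        ])
        per_strand[strand] = (ref, offs, what, coords, k, dinucs)

    names = ["U"] + [sample_name(t) for t in cfg.timepoints]
    times = [None] + list(cfg.timepoints)
    samples: dict[str, list[Read]] = {}
    truth_rows = []
    depth_rows = []
    q0 = cfg.lesions_per_molecule

    for name, t in zip(names, times):
        n_ts = int(rng.binomial(cfg.reads_per_sample, 0.5))
        n_by_strand = {"TS": n_ts, "NTS": cfg.reads_per_sample - n_ts}
        reads: list[Read] = []
        for strand in ("TS", "NTS"):
            ref, offs, what, coords, k, dinucs = per_strand[strand]
            n = n_by_strand[strand]
            if t is None:
                lesion_counts = np.zeros(offs.size, dtype=np.int64)
                n_full = n
            else:
                p = q0 * what * np.exp(-k * t)
                probs = np.concatenate([p, [1.0 - p.sum()]])
                draw = rng.multinomial(n, probs)
                lesion_counts, n_full = draw[:-1], int(draw[-1])
            bg = rng.poisson(cfg.background_rate, size=offs.size)
            total = lesion_counts + bg
            serial = 0
            for j, c in zip(offs, total):
                if c == 0:
                    continue
                seq = ref.sequence[:int(j)]
                qual = constant_quality(len(seq), cfg.read_quality)
                for _ in range(int(c)):
                    reads.append(Read(
                        f"{gene.name}:{strand}:{name}:{serial} cap={strand}", seq, qual))
                    serial += 1
            full_seq = ref.sequence
            full_qual = constant_quality(len(full_seq), cfg.read_quality)
            for _ in range(n_full):
                reads.append(Read(
                    f"{gene.name}:{strand}:{name}:{serial} cap={strand}",
                    full_seq, full_qual))
                serial += 1
            expected = (np.zeros(offs.size) if t is None
                        else n * q0 * what * np.exp(-k * t)) + cfg.background_rate
            for j, c, lc, b, coord, exp_c in zip(
                    offs, total, lesion_counts, bg, coords, expected):
                if c or exp_c:
                    truth_rows.append((gene.name, strand, name, int(coord),
                                       int(lc), int(b), int(c), float(exp_c)))
            depth_rows.append((gene.name, strand, name, n + int(bg.sum())))
        samples[name] = reads

    truth = pd.DataFrame(
        truth_rows, columns=["gene", "strand", "sample", "site",
                             "lesion_count", "background_count", "count",
                             "expected_count"])
    depths = pd.DataFrame(depth_rows, columns=["gene", "strand", "sample", "depth"])
    return samples, GroundTruth(repair=truth, depths=depths)


def write_lesion_fastq(samples: Mapping[str, list[Read]], prefix: str) -> list[str]:
    paths = []
    for name, reads in samples.items():
        path = f"{prefix}_{name}.fastq"
        write_fastq(path, reads)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# screen branch
# ---------------------------------------------------------------------------

DEFAULT_FLANK5 = "ACGTGCTAGCAC"
DEFAULT_FLANK3 = "GTCACGGATCCA"


def demo_orf(n_codons: int = 172, seed: int = 406) -> str:
    """Synthetic ORF stand-in for the screened gene (start codon, 171 sense
    codons, stop); the real coding sequence is not bundled."""
    rng = np.random.default_rng(seed)
    codons = ["ATG"] + [SENSE_CODONS[i] for i in
                        rng.integers(0, len(SENSE_CODONS), size=n_codons - 1)]
    if n_codons >= 149:
        codons[148] = "GGT"  # glycine at codon 149, the worked-example position
    return "".join(codons) + "TAA"


def random_codon_library(
    orf_sequence: str,
    rng: np.random.Generator,
    n_variants: int = 1500,
    total_freq: float = 0.85,
    mutable_codons: tuple[int, int] = (2, 171),
) -> dict[tuple[int, str], float]:
    """Random single-codon substitution library (error-prone-PCR style)."""
    lo, hi = mutable_codons
    lib: dict[tuple[int, str], float] = {}
    while len(lib) < n_variants:
        pos = int(rng.integers(lo, hi + 1))
        ref_codon = orf_sequence[3 * (pos - 1):3 * pos]
        codon = ALL_CODONS[int(rng.integers(len(ALL_CODONS)))]
        if codon != ref_codon:
            lib[(pos, codon)] = 0.0
    freqs = rng.dirichlet(np.ones(len(lib))) * total_freq
    for key, f in zip(sorted(lib), freqs):
        lib[key] = float(f)
    return {k: lib[k] for k in sorted(lib)}


@dataclass
class ScreenSimConfig:
    """Study conditions for the UV-selection screen.

    ``variant_effects`` maps (codon position, amino acid) to a UV survival
    multiplier (1 = neutral); ``library_frequencies`` maps (position, codon)
    to pre-selection frequency (remaining mass is wild type; None draws a
    random library).  ``batch_depth_factors`` / ``batch_dispersion`` are the
    per-replicate multiplicative depth and composition perturbations.
    """

    orf_sequence: str = field(default_factory=demo_orf)
    flank5: str = DEFAULT_FLANK5
    flank3: str = DEFAULT_FLANK3
    mutable_codons: tuple[int, int] = (2, 171)
    variant_effects: Mapping[tuple[int, str], float] = field(default_factory=dict)
    library_frequencies: Mapping[tuple[int, str], float] | None = None
    replicates: int = 3
    batch_depth_factors: Sequence[float] = (1.0, 0.9, 1.1)
    batch_dispersion: float = 0.05
    per_base_error: float = 1e-3
    reads_per_arm: int = 100_000
    read_length: int = 300
    read_quality: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")
        if any(m < 0 for m in self.variant_effects.values()):
            raise ValueError("survival multipliers must be >= 0")
        if self.library_frequencies is not None:
            s = sum(self.library_frequencies.values())
            if s > 1 + 1e-9:
                raise ValueError(f"library frequencies sum to {s} > 1")
        amp = len(self.flank5) + len(self.orf_sequence) + len(self.flank3)
        if not self.read_length <= amp <= 2 * self.read_length:
            raise ValueError("mates must overlap: need read_length <= amplicon "
                             "<= 2*read_length")

    @property
    def amplicon(self) -> str:
        return self.flank5 + self.orf_sequence + self.flank3


@dataclass
class PairedReadSet:
    """Paired-end reads for one sample, stored as (n, L) uint8 base matrices."""

    sample: str
    r1: np.ndarray
    r2: np.ndarray
    quality: int = 40

    def __len__(self) -> int:
        return self.r1.shape[0]

    def to_reads(self) -> list[tuple[Read, Read]]:
        q1 = constant_quality(self.r1.shape[1], self.quality)
        q2 = constant_quality(self.r2.shape[1], self.quality)
        out = []
        for i in range(len(self)):
            rid = f"{self.sample}:{i}"
            out.append((Read(rid + "/1", self.r1[i].tobytes().decode(), q1),
                        Read(rid + "/2", self.r2[i].tobytes().decode(), q2)))
        return out

    def write_fastq(self, path_r1: str, path_r2: str) -> None:
        pairs = self.to_reads()
        write_fastq(path_r1, (a for a, _ in pairs))
        write_fastq(path_r2, (b for _, b in pairs))


def _apply_errors(mat: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    """In-place uniform substitution errors (always to a different base)."""
    n, L = mat.shape
    if n == 0 or rate <= 0:
        return
    n_err = rng.binomial(n * L, rate)
    if n_err == 0:
        return
    rows = rng.integers(0, n, size=n_err)
    cols = rng.integers(0, L, size=n_err)
    shift = rng.integers(1, 4, size=n_err)
    mat[rows, cols] = _BASES[(_ENCODE[mat[rows, cols]] + shift) % 4]


def simulate_screen_reads(
    cfg: ScreenSimConfig,
) -> tuple[dict[str, PairedReadSet], GroundTruth]:
    """Simulate {no-UV, UV} x replicates paired-end amplicon read sets.

    UV-arm variant frequencies are pre-frequency x survival multiplier,
    renormalized; the no-UV arm keeps pre-frequencies.  Reads are drawn
    multinomially at ``reads_per_arm`` (scaled by the replicate depth factor)
    with per-base substitution errors.
    """
    if cfg.reads_per_arm <= 0:
        raise ValueError("reads_per_arm must be positive")
    rng = np.random.default_rng(cfg.seed)
    lib = cfg.library_frequencies
    if lib is None:
        lib = random_codon_library(cfg.orf_sequence, rng,
                                   mutable_codons=cfg.mutable_codons)
    variants = sorted(lib)
    f = np.array([lib[v] for v in variants])
    f_wt = 1.0 - f.sum()
    mult = np.array([
        cfg.variant_effects.get((pos, CODON_TABLE[codon]), 1.0)
        for pos, codon in variants
    ])

    # per-variant amplicons and mate templates
    amp = sequences_to_matrix([cfg.amplicon])[0]
    V, A = len(variants), amp.size
    amps = np.tile(amp, (V + 1, 1))
    off = len(cfg.flank5)
    for i, (pos, codon) in enumerate(variants):
        amps[i, off + 3 * (pos - 1):off + 3 * pos] = np.frombuffer(
            codon.encode(), dtype=np.uint8)
    L = cfg.read_length
    tmpl_r1 = amps[:, :L]
    tmpl_r2 = _COMP[amps[:, A - L:]][:, ::-1]

    expected_fc = mult / (f @ mult + f_wt)
    samples: dict[str, PairedReadSet] = {}
    truth = pd.DataFrame({
        "position": [p for p, _ in variants],
        "codon": [c for _, c in variants],
        "aa": [CODON_TABLE[c] for _, c in variants],
        "pre_freq": f,
        "multiplier": mult,
        "expected_fc": expected_fc,
    })

    depth_factors = list(cfg.batch_depth_factors)
    while len(depth_factors) < cfg.replicates:
        depth_factors.append(1.0)

    for r in range(1, cfg.replicates + 1):
        z = rng.normal(size=V)
        g = f * np.exp(cfg.batch_dispersion * z)
        if g.sum() > 0:
            g *= f.sum() / g.sum()
        n_reads = max(1, int(round(cfg.reads_per_arm * depth_factors[r - 1])))
        for arm, weights in (("noUV", np.concatenate([g, [f_wt]])),
                             ("UV", np.concatenate([g * mult, [f_wt]]))):
            p = weights / weights.sum()
            counts = rng.multinomial(n_reads, p)
            idx = np.repeat(np.arange(V + 1), counts)
            r1 = tmpl_r1[idx].copy()
            r2 = tmpl_r2[idx].copy()
            _apply_errors(r1, cfg.per_base_error, rng)
            _apply_errors(r2, cfg.per_base_error, rng)
            name = f"{arm}_r{r}"
            samples[name] = PairedReadSet(name, r1, r2, cfg.read_quality)
            truth[f"count_{name}"] = counts[:-1]

    return samples, GroundTruth(screen=truth)
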