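"""Read merging, codon-variant calling and counting for the screen branch."""

import numpy as np
import pytest

from repairscreen.fastq import Read, constant_quality
from repairscreen.genes import revcomp, sequences_to_matrix
from repairscreen.screen_reads import (
    CodonCountMatrix,
    MergedRead,
    OrfReference,
    call_codon_variants,
    call_variants_bulk,
    count_codon_variants,
    merge_pair,
    merge_pairs_bulk,
    merge_read_pairs,
)
from repairscreen.simulate import (
    CODON_TABLE,
    PairedReadSet,
    ScreenSimConfig,
    demo_orf,
    simulate_screen_reads,
)

from conftest import make_read


def make_pair(template: str, L: int) -> tuple[Read, Read]:
    return make_read(template[:L], "p/1"), make_read(revcomp(template)[:L], "p/2")


class TestMergePair:
    def test_perfect_overlap_reconstructs_template(self):
        rng = np.random.default_rng(0)
        template = "".join(rng.choice(list("ACGT"), size=150))
        r1, r2 = make_pair(template, 100)  # 50 nt overlap
        res = merge_pair(r1, r2, min_overlap=20)
        assert isinstance(res, MergedRead)
        assert res.seq == template
        assert res.overlap == 50 and res.mismatches == 0

    def test_overlap_mismatch_resolved_toward_higher_quality(self):
        rng = np.random.default_rng(1)
        template = "".join(rng.choice(list("ACGT"), size=150))
        r1, r2 = make_pair(template, 100)
        # flip one overlap base on mate 2; mate 1 gets the higher quality
        seq2 = list(r2.seq)
        pos2 = len(seq2) - 1 - 30  # within the overlap after revcomp
        orig = seq2[pos2]
        seq2[pos2] = {"A": "C", "C": "A", "G": "T", "T": "G"}[orig]
        r2_low = Read(r2.id, "".join(seq2), constant_quality(100, 20))
        res = merge_pair(r1, r2_low, min_overlap=20)
        assert isinstance(res, MergedRead)
        assert res.mismatches == 1
        assert res.seq == template  # mate-1 base won

    def test_mate2_base_wins_when_its_quality_higher(self):
        rng = np.random.default_rng(5)
        template = "".join(rng.choice(list("ACGT"), size=150))
        r1, r2 = make_pair(template, 100)
        seq1 = list(r1.seq)
        seq1[80] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq1[80]]
        r1_low = Read(r1.id, "".join(seq1), constant_quality(100, 20))
        res = merge_pair(r1_low, r2, min_overlap=20)
        assert isinstance(res, MergedRead)
        assert res.seq == template

    def test_short_overlap_rejected(self):
        rng = np.random.default_rng(2)
        template = "".join(rng.choice(list("ACGT"), size=195))
        r1, r2 = make_pair(template, 100)  # true overlap 5 nt
        res = merge_pair(r1, r2, min_overlap=20)
        assert res == (r1.id, "short_overlap")

    def test_empty_read_rejected(self):
        res = merge_pair(make_read(""), make_read("ACGT"))
        assert res[1] == "empty"

    def test_merge_read_pairs_partitions_input(self):
        rng = np.random.default_rng(3)
        good = make_pair("".join(rng.choice(list("ACGT"), size=150)), 100)
        bad = make_pair("".join(rng.choice(list("ACGT"), size=195)), 100)
        merged, rejected = merge_read_pairs([good, bad], min_overlap=20)
        assert len(merged) == 1 and len(rejected) == 1


class TestBulkMerge:
    def test_bulk_equals_per_read_reference(self):
        """The vectorized merge must reproduce the per-read routine."""
        rng = np.random.default_rng(7)
        cfg = ScreenSimConfig(reads_per_arm=400, per_base_error=5e-3, seed=11)
        samples, _ = simulate_screen_reads(cfg)
        rs = samples["UV_r1"]
        merged_mat, strays, n_rej = merge_pairs_bulk(rs)
        bulk = sorted([row.tobytes().decode() for row in merged_mat] + strays)
        ref_merged, ref_rej = merge_read_pairs(rs.to_reads())
        assert sorted(m.seq for m in ref_merged) == bulk
        assert len(ref_rej) == n_rej


ORF = demo_orf()
REF = OrfReference(ORF, "ACGTGCTAGCAC", "GTCACGGATCCA")


def amplicon(orf: str = ORF) -> str:
    return REF.flank5 + orf + REF.flank3


class TestCallCodonVariants:
    def test_reference_read_yields_no_calls(self):
        assert call_codon_variants(amplicon(), REF) == []

    def test_gly149_to_asp_called(self):
        # codon 149 is GGT; G->A at its second base encodes Asp
        orf = list(ORF)
        assert ORF[3 * 148:3 * 149] == "GGT"
        orf[3 * 148 + 1] = "A"
        calls = call_codon_variants(amplicon("".join(orf)), REF)
        assert [(c.position, c.aa) for c in calls] == [(149, "D")]
        assert not calls[0].synonymous

    def test_synonymous_change_flagged(self):
        orf = list(ORF)
        orf[3 * 148 + 2] = "A"  # GGT -> GGA, still glycine
        calls = call_codon_variants(amplicon("".join(orf)), REF)
        assert calls[0].synonymous and calls[0].aa == "G"

    def test_double_mutant_reports_both(self):
        orf = list(ORF)
        orf[3 * 110] = "T" if orf[3 * 110] != "T" else "A"    # codon 111
        orf[3 * 112] = "T" if orf[3 * 112] != "T" else "A"    # codon 113
        calls = call_codon_variants(amplicon("".join(orf)), REF)
        assert [c.position for c in calls] == [111, 113]

    def test_missing_anchor_rejected(self):
        res = call_codon_variants(ORF, REF)  # no flanks at all
        assert res == (None, "no_anchor_5")

    def test_mutation_outside_mutable_range_ignored(self):
        orf = list(ORF)
        orf[0] = "C"  # codon 1
        calls = call_codon_variants(amplicon("".join(orf)), REF)
        assert calls == []

    def test_bulk_equals_per_read_reference(self):
        rng = np.random.default_rng(13)
        seqs = []
        expected = []
        for _ in range(50):
            orf = list(ORF)
            for _ in range(rng.integers(0, 4)):
                orf[rng.integers(len(orf))] = "ACGT"[rng.integers(4)]
            seq = amplicon("".join(orf))
            seqs.append(seq)
            expected.append(call_codon_variants(seq, REF))
        calls, rejected = call_variants_bulk(sequences_to_matrix(seqs), REF)
        assert rejected == 0
        assert calls == expected


class TestCounting:
    def _calls(self, *variants):
        from repairscreen.screen_reads import VariantCall
        return [VariantCall(p, c, a, False) for p, c, a in variants]

    def test_single_variant_counts_in_both_modes(self):
        reads = [self._calls((149, "GAT", "D"))] * 10
        for mode in ("marginal", "single_only"):
            m = count_codon_variants({"s": reads}, mode)
            assert m.counts["count"].sum() == 10
            assert m.depths["s"] == 10

    def test_double_mutant_mode_dependence(self):
        reads = [self._calls((111, "ATT", "I"), (113, "GAT", "D"))]
        marginal = count_codon_variants({"s": reads}, "marginal")
        single = count_codon_variants({"s": reads}, "single_only")
        assert marginal.counts["count"].sum() == 2
        assert single.counts.empty
        assert single.depths["s"] == 1  # still countable depth

    def test_no_reads_gives_empty_matrix(self):
        m = count_codon_variants({"s": []})
        assert m.counts.empty and m.depths["s"] == 0

    def test_unknown_mode_raises(self):
        with pytest.raises(ValueError):
            count_codon_variants({}, "both")


def test_error_free_pipeline_counts_match_brute_force_oracle():
    """On error-free reads, pipeline counts equal a per-read string-comparison
    oracle implemented independently here."""
    from collections import Counter

    from repairscreen.screen_reads import screen_counts_from_readsets

    cfg = ScreenSimConfig(reads_per_arm=500, per_base_error=0.0, seed=23)
    samples, _ = simulate_screen_reads(cfg)
    matrix, log = screen_counts_from_readsets(
        samples, OrfReference(cfg.orf_sequence, cfg.flank5, cfg.flank3))
    assert log[["rejected_merge", "rejected_anchor"]].to_numpy().sum() == 0

    oracle: dict[str, Counter] = {}
    for name, rs in samples.items():
        c = Counter()
        for r1, r2 in rs.to_reads():
            # reconstruct the molecule: mates overlap by 2L - amplicon length
            ov = 2 * len(r1.seq) - len(cfg.amplicon)
            mol = r1.seq + revcomp(r2.seq)[ov:]
            orf = mol[len(cfg.flank5):len(mol) - len(cfg.flank3)]
            for pos in range(2, 172):
                codon = orf[3 * (pos - 1):3 * pos]
                if codon != cfg.orf_sequence[3 * (pos - 1):3 * pos]:
                    c[(pos, codon)] += 1
        oracle[name] = c

    got = matrix.counts.set_index(["sample", "position", "codon"])["count"]
    for name, c in oracle.items():
        for (pos, codon), n in c.items():
            assert got.loc[(name, pos, codon)] == n
        assert got.xs(name, level="sample").sum() == sum(c.values())
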