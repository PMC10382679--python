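# Methods

`repairscreen` implements the computational halves of two assays used to
dissect transcription-coupled nucleotide excision repair (TCR) in budding
yeast: (A) a UV-selection deep-mutational-scanning screen over a codon
substitution library, scored with a nonparametric enrichment statistic, and
(B) strand-specific mapping of UV-induced cyclobutane pyrimidine dimers
(CPDs) with repair-kinetics quantification. A read-level simulator generates
both kinds of data with known ground truth, so every downstream stage is
testable without external downloads.

## A. Screen branch

### Read processing

Paired 300-nt amplicon mates are joined over their best-scoring overlap
(matches minus mismatches, maximized over all overlaps at least
`min_overlap = 20` nt; ties go to the longer overlap). Overlap disagreements
are resolved toward the higher base quality, with mate 1 winning ties. Pairs
with no acceptable overlap (mismatch fraction above `max_mismatch_frac =
0.1`) are rejected with a reason. On repetitive templates the maximal-score
rule can legitimately select a longer-than-true perfect overlap; amplicon
data do not exercise this case.

The reading frame is anchored by exact matches of fixed 12-nt flanks on
either side of the ORF. Reads missing an anchor, or whose enclosed ORF
length differs from the reference (indels), are dropped, never shifted.
Every codon in the mutable range (positions 2-171) whose triplet differs
from the reference is reported with its standard-genetic-code translation;
synonymous changes are flagged but carry the reference amino acid.

Counting is `marginal` by default (every mutated codon of a read counts),
because error-prone PCR yields multi-hit molecules; `single_only` (only
reads with exactly one mutated codon) is available for sensitivity analysis.
Depth per sample is all merged, anchored reads, including wild type.

The pipeline-scale path operates on uint8 base matrices (vectorized merge
with a 16-nt seed plus a per-read fallback, column-wise codon diffing); the
per-read routines define the contract and the suite asserts the two routes
agree exactly.

### Enrichment statistic

Counts are converted to per-million abundances with a pseudocount of 0.5
(`(count + 0.5) / depth * 1e6`). Batch variation between replicates is
removed by median-log-ratio centering to the across-sample geometric-mean
profile, with the correction factors mean-centered so the overall scale is
preserved and the operation is idempotent. This is a deliberately simple
stand-in for full array/seq batch-effect decomposition methods and is
labelled as such in output metadata.

For each variant, with condition means `mu_UV` and `mu_ctrl`:

    M = log2(mu_UV / mu_ctrl),  D = |mu_UV - mu_ctrl|,  theta = (M + D) / 2.

The noise distribution pools (|M*|, D*) over all within-condition replicate
pairs across all variants; a variant's probability is the fraction of noise
points strictly dominated in both coordinates by its (|M|, D). Strict
inequalities make the degenerate case M = D = 0 give probability 0. Hits
are `M > 1 and probability > 0.98` (strict, configurable); the depleted list
is the mirror image at `M < -1`. Coverage counts all 20 amino acids at each
of the 170 mutable positions (a 3,400-variant space), including
synonymous-to-reference identities.

## B. Repair branch

### Lesion mapping

Each gene is a restriction-released fragment with a TSS-anchored coordinate
frame: +1 is the first transcribed base, there is no position 0, and the
transcribed strand (TS) is the bottom strand of the stored top-strand
sequence. Strand references run 5'->3' along each strand with a bijective
offset-to-coordinate map.

The assay chemistry cuts immediately 5' of each CPD, so a read is the
strand reference prefix ending just 5' of the lesion; the read's 3'-terminal
base is the adapter-ligation junction. Reads are placed by anchored prefix
search (up to 2 substitutions; identical sequences are memoized). The lesion
is assigned to the dinucleotide immediately 3' of the junction and keyed by
the coordinate of its 5' base on that strand; junctions at the fragment 3'
end ("edge" — intact, lesion-free molecules) and non-dipyrimidine
dinucleotides are rejected with reasons. Reads matching both strands are
resolved by the strand-specific capture label in the read header or dropped
as ambiguous.

Per-sample depth is every read mapped to the strand, including edge-rejected
full-length molecules. Those intact fragments are the stable sequencing
anchor: they make depth proportional to molecules sampled rather than to
surviving lesions, so depth normalization does not cancel a uniform repair
signal.

### Quantification

Each sample is scaled to the unirradiated control's depth; the scaled
control (background incision) counts are subtracted per site and negatives
floored at 0. Percent CPDs remaining at time t is `100 * adjusted(t) /
adjusted(0)`; sites with adjusted time-0 counts below `min_t0 = 5` are
masked (`low_t0`) to avoid ratio blow-ups. Both thresholds are configurable.

Aggregates are unweighted means over qualifying unmasked sites - either all
sites strictly beyond +50 (the cutoff is read as exclusive; configurable) or
sites inside annotated nucleosome core/linker intervals. Unweighted rather
than count-weighted means were chosen so high-yield TT sites do not dominate
the profile; this is a declared choice, not a derived one.

Genotype comparisons use the classical paired Student's t test on per-gene
aggregate means at each timepoint (df = n - 1; two-sided; stars at p < 0.05
and p < 0.01; all-zero differences give t = 0, p = 1 by convention, and no
multiple-testing correction is applied). TCR-enhancement levels threshold
the mean reduction (wild-type minus mutant, percentage points, over genes x
rule timepoints): the three-timepoint rule (0.5, 1, 3 h) calls levels 3/2/1
at reductions of at least 30/20/10 points, the two-timepoint rule (0.5, 1 h)
calls 2/1 at 20/10; anything smaller is level 0.

### Pseudo-gels

Per-site counts render as grayscale band images: one lane per sample
(control "U" first, then timepoints), one band row per site in ascending
coordinate, darkness `(count / max)^gamma` normalized to the per-image
maximum (gamma 0.7 mimics film response; purely cosmetic). Rendering is a
pure function of the table and spec.

## Simulator

The simulator defines the study conditions; its defaults are fixed.

*Lesion branch.* UV dose 120 J/m2 (record-keeping). CPD induction weights
default TT:TC:CT:CC = 68:16:13:3, a literature-typical yield spectrum.
Each captured molecule carries at most one lesion, drawn with probability
`lesions_per_molecule = 0.2` at a site proportional to induction weights;
there is no re-damage, so per-site expectations are exactly
`N * q0 * w_i * exp(-k_i t)`. Repair rates are looked up by (gene, strand,
nucleosome region, genotype) with wildcards. Background incisions are
Poisson with uniform per-site rate in every sample; the unirradiated control
contains only background. Sites closer than 20 nt to the capture boundary
are not recovered (capture-oligo footprint), which also keeps the
end-to-end count oracle exact. Timepoints are {0, 0.5, 1, 3} h plus the
control; default depth 2e5 molecules per sample.

*Screen branch.* An error-prone-PCR-style library of ~1,500 random
single-codon substitutions totalling 85% of molecules (the rest wild type),
three replicates, 1e5 read pairs per arm, per-base substitution error 1e-3,
per-replicate depth factors (1.0, 0.9, 1.1) and lognormal composition
jitter (sigma 0.05) shared between a replicate's two arms. UV-arm
frequencies are pre-frequency times survival multiplier, renormalized;
outgrowth is effect-neutral. Real screens of this design do not publish
their sequencing depth or selection bottleneck, so these depths are declared
defaults chosen to give tens-to-hundreds of counts per variant.

All randomness flows from one integer seed through a single generator with a
documented stream order (samples in declared order; within a sample the
strand split, lesion multinomial, then background Poisson; for the screen,
per replicate the jitter then per arm the multinomial and error draws), so
identical configs are byte-identical.

What the simulator does not emulate: PCR duplicates, indels, quality-score
error profiles, 6-4 photoproducts, lesion interference (multi-lesion
molecules), transcription-level differences between the three genes, and
chromatin effects beyond the fixed nucleosome intervals. Passing tests
therefore demonstrate correctness of the analysis arithmetic and its
statistical calibration under these idealized conditions, not performance on
real sequencing artifacts.

## Problem sizes and numerical choices

The test suite and acceptance script run at: null calibration, five screens
at 1e5 pairs/arm x 3 replicates; planted-hit recovery, ten screens at 5e4
pairs/arm with a 4x survivor at 1% pre-frequency; half-life recovery, ten
lesion runs at 2e5 reads/sample with background ~2% of mean per-site signal;
oracle-equality checks on error-free runs of a few thousand reads. These
sizes give comfortable statistical margins for each property while keeping
a full run in minutes on one core.

Degenerate inputs are defined rather than left to chance: empty reads
reject with a reason; zero control depth and missing time-0 samples raise;
all-zero gel tables render uniform background with a warning; a single
replicate passes batch correction unchanged with a warning; variants absent
from both conditions are excluded with a log entry. Ties in merge scoring go
to the longer overlap; equal-quality overlap conflicts go to mate 1.

## Known limitations

- The enrichment probability is estimated from replicate-pair noise with
  three replicates; its resolution is bounded by the pooled noise size, and
  very sparse variants (expected counts of a few reads) have noisy M.
- The simplified batch centering removes only global per-sample scale, not
  variant-specific batch interactions.
- The aligner is an anchored prefix search for short known fragments; it
  does not handle indels or genome-scale references, by design.
- Per-site percent remaining is a ratio estimator; at the masking threshold
  (adjusted t0 counts near 5) it is biased upward by a few percent, which is
  why aggregate curves sit slightly above the per-site exponential truth.
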