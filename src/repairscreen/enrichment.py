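"""Enrichment/depletion statistics for the UV-selection screen.

For each variant v (codon position x amino acid) with corrected normalized
abundances, the statistic compares condition means mu_UV and mu_ctrl:

    M     = log2(mu_UV / mu_ctrl)          (log2 fold change)
    D     = |mu_UV - mu_ctrl|
    theta = (M + D) / 2

The "probability" that a variant's signal exceeds replicate noise is the
empirical fraction of within-condition replicate-pair contrasts (|M*|, D*) -
pooled over all variants and both conditions - strictly dominated by the
variant's (|M|, D).  This is a reimplementation of the nonparametric
differential-signal convention popularized by the NOISeq package; hits are
variants with M > 1 and probability > 0.98 (strict, configurable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .screen_reads import AMINO_ACIDS, CodonCountMatrix


def coverage_summary(
    matrix: CodonCountMatrix, min_count: int = 1
) -> tuple[int, float]:
    """Covered variant count and percent of the 20 x positions variant space.

    A variant is a (codon position, amino acid) pair over the mutable range;
    all 20 amino acids count at every position (synonymous-to-reference
    identities included), so the default 2-171 range spans 3400 variants.
    Covered means pooled count across samples >= ``min_count``.  The percent
    is reported to one decimal.
    """
    lo, hi = matrix.mutable_codons
    space = 20 * (hi - lo + 1)
    pooled = matrix.pooled_aa_counts()
    covered = 0
    for (pos, aa), n in pooled.items():
        if lo <= pos <= hi and aa in AMINO_ACIDS and n >= min_count:
            covered += 1
    return covered, round(100.0 * covered / space, 1)


def normalize_counts(
    matrix: CodonCountMatrix, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Counts -> per-million normalized abundances, (count + pc) / depth * 1e6."""
    counts = matrix.by_amino_acid()
    depths = matrix.depths.reindex(counts.columns)
    if (depths <= 0).any():
        bad = list(depths.index[depths <= 0])
        raise ValueError(f"zero depth in samples {bad}")
    return (counts + pseudocount).div(depths, axis=1) * 1e6


def correct_batches(abundances: pd.DataFrame) -> pd.DataFrame:
    """Median-log-ratio centering of each sample to the geometric-mean profile.

    A simplified batch-correction: each sample is divided by the exponential
    of its median log-ratio to the across-sample geometric mean profile, with
    the factors mean-centered so the overall scale is preserved and the
    operation is idempotent.  This removes global per-sample scale shifts
    while leaving sparse variant-level signal intact; it is NOT the ARSyN
    algorithm (documented in output metadata by callers).
    """
    if abundances.shape[1] < 2:
        warnings.warn("batch correction needs >= 2 samples; returning input")
        return abundances.copy()
    logs = np.log(abundances.to_numpy())
    ref = logs.mean(axis=1, keepdims=True)
    m = np.median(logs - ref, axis=0)
    m = m - m.mean()
    return abundances / np.exp(m)


def _condition_of(sample: str) -> str:
    return sample.split("_")[0]


def compute_enrichment(
    abundances: pd.DataFrame,
    condition_map: Mapping[str, str] | None = None,
    uv_label: str = "UV",
    ctrl_label: str = "noUV",
) -> pd.DataFrame:
    """Per-variant M, D, theta and empirical non-noise probability.

    ``condition_map`` assigns each sample column to a condition; by default
    the token before the first underscore in the column name is used
    (``UV_r1`` -> ``UV``).  Variants with zero abundance in both conditions
    are excluded.  Requires >= 2 replicates per condition.
    """
    cond = {s: (condition_map[s] if condition_map else _condition_of(s))
            for s in abundances.columns}
    uv_cols = [s for s in abundances.columns if cond[s] == uv_label]
    ctrl_cols = [s for s in abundances.columns if cond[s] == ctrl_label]
    if len(uv_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("need >= 2 replicates per condition")

    keep = abundances[uv_cols + ctrl_cols].gt(0).any(axis=1)
    if (~keep).any():
        warnings.warn(f"excluding {(~keep).sum()} variant(s) with no abundance "
                      "in either condition")
    ab = abundances.loc[keep]

    mu_uv = ab[uv_cols].mean(axis=1).to_numpy()
    mu_ctrl = ab[ctrl_cols].mean(axis=1).to_numpy()
    with np.errstate(divide="ignore"):
        M = np.log2(mu_uv / mu_ctrl)
    D = np.abs(mu_uv - mu_ctrl)

    noise_m = []
    noise_d = []
    for cols in (uv_cols, ctrl_cols):
        for a, b in combinations(cols, 2):
            x = ab[a].to_numpy()
            y = ab[b].to_numpy()
            with np.errstate(divide="ignore"):
                noise_m.append(np.abs(np.log2(x / y)))
            noise_d.append(np.abs(x - y))
    nm = np.concatenate(noise_m)
    nd = np.concatenate(noise_d)

    absM = np.abs(M)
    prob = np.empty(absM.size)
    chunk = 2048
    for start in range(0, absM.size, chunk):
        sl = slice(start, min(start + chunk, absM.size))
        dominated = (nm[None, :] < absM[sl, None]) & (nd[None, :] < D[sl, None])
        prob[sl] = dominated.mean(axis=1)

    out = pd.DataFrame({"M": M, "D": D, "theta": (M + D) / 2.0,
                        "probability": prob}, index=ab.index)
    return out.sort_values("theta", ascending=False)


def filter_hits(
    table: pd.DataFrame, m_min: float = 1.0, p_min: float = 0.98
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Enriched hits (M > m_min, probability > p_min; theta descending) and
    the symmetric depleted list (M < -m_min; theta ascending). Strict."""
    enriched = table[(table["M"] > m_min) & (table["probability"] > p_min)]
    depleted = table[(table["M"] < -m_min) & (table["probability"] > p_min)]
    return (enriched.sort_values("theta", ascending=False),
            depleted.sort_values("theta", ascending=True))


class ScreenEnrichment:
    """Enrichment model over a codon count matrix (statsmodels-style).

    Parameters
    ----------
    counts
        :class:`CodonCountMatrix` with UV/no-UV x replicate samples.
    pseudocount
        Added to every count before normalization and log (default 0.5).
    batch_correct
        Apply the simplified median-log-ratio centering (default True).
    """

    def __init__(self, counts: CodonCountMatrix, pseudocount: float = 0.5,
                 batch_correct: bool = True,
                 condition_map: Mapping[str, str] | None = None):
        self.counts = counts
        self.pseudocount = pseudocount
        self.batch_correct = batch_correct
        self.condition_map = condition_map

    def fit(self, m_min: float = 1.0, p_min: float = 0.98) -> "EnrichmentResults":
        ab = normalize_counts(self.counts, self.pseudocount)
        if self.batch_correct:
            ab = correct_batches(ab)
        table = compute_enrichment(ab, self.condition_map)
        table["hit"] = (table["M"] > m_min) & (table["probability"] > p_min)
        return EnrichmentResults(self, table, ab, m_min, p_min)


@dataclass
class EnrichmentResults:
    """Fitted enrichment table plus hit calls and a text summary."""

    model: ScreenEnrichment
    table: pd.DataFrame
    abundances: pd.DataFrame = field(repr=False)
    m_min: float = 1.0
    p_min: float = 0.98

    def hits(self) -> pd.DataFrame:
        return filter_hits(self.table, self.m_min, self.p_min)[0]

    def depleted(self) -> pd.DataFrame:
        return filter_hits(self.table, self.m_min, self.p_min)[1]

    def coverage(self, min_count: int = 1) -> tuple[int, float]:
        return coverage_summary(self.model.counts, min_count)

    def summary(self, top: int = 10) -> str:
        covered, pct = self.coverage()
        lo, hi = self.model.counts.mutable_codons
        lines = [
            "UV-selection screen enrichment",
            "==============================",
            f"variants scored: {len(self.table)}",
            f"variant space covered: {covered} ({pct}% of "
            f"{20 * (hi - lo + 1)})",
            f"hit rule: log2FC > {self.m_min} and probability > {self.p_min} "
            f"(strict); hits: {int(self.table['hit'].sum())}",
            f"batch correction: "
            f"{'median-log-ratio centering (simplified; not ARSyN)' if self.model.batch_correct else 'none'}",
            "",
            f"top {top} by theta:",
            self.table.head(top).to_string(
                float_format=lambda x: f"{x:.3f}"),
        ]
        return "\n".join(lines)

    def to_tsv(self, path: str) -> None:
        out = self.table.reset_index()
        out.to_csv(path, sep="\t", index=False)
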