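"""Repair kinetics from strand-specific lesion counts.

Per-site percent CPDs remaining is the ratio of background-subtracted,
depth-normalized lesion counts at time t to time 0, x100.  Aggregates are
unweighted means over qualifying sites - either all sites more than a cutoff
(default +50) downstream of the TSS, or sites inside nucleosome core/linker
intervals.  Between-genotype comparisons use the classical paired Student's t
test (pairing over genes at each timepoint) and ordinal
transcription-coupled-repair (TCR) enhancement levels thresholded on the mean
reduction in percent remaining.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genes import GeneModel
from .lesionmap import LesionCountTable


def normalize_and_subtract(
    table: LesionCountTable, control: str = "U"
) -> pd.DataFrame:
    """Depth-normalize each sample to the control and subtract its background.

    Each sample's per-site counts are scaled by (control depth / sample
    depth); the scaled control counts are then subtracted from every
    irradiated sample and negatives are floored at 0.  Returns the adjusted
    site x sample table (control column removed).
    """
    if control not in table.counts.columns:
        raise ValueError(f"control sample {control!r} missing")
    depths = table.depth
    if depths[control] <= 0:
        raise ValueError("control depth is zero")
    if (depths <= 0).any():
        raise ValueError("zero-depth sample")
    scaled = table.counts * (float(depths[control]) / depths)
    bg = scaled[control]
    adjusted = scaled.drop(columns=[control]).sub(bg, axis=0).clip(lower=0.0)
    return adjusted


def percent_remaining(
    adjusted: pd.DataFrame, t0: str = "0h", min_t0: float = 5.0
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-site percent CPDs remaining relative to the time-0 sample.

    Sites whose adjusted time-0 count is below ``min_t0`` are masked (reason
    ``low_t0``) to avoid ratio blow-ups.  Returns (percent table with masked
    rows as NaN, mask-reason series).
    """
    if t0 not in adjusted.columns:
        raise ValueError(f"time-0 sample {t0!r} missing")
    base = adjusted[t0]
    masked = base < min_t0
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = adjusted.div(base, axis=0) * 100.0
    pct[masked] = np.nan
    reasons = pd.Series(np.where(masked, "low_t0", ""), index=adjusted.index,
                        name="mask_reason")
    return pct, reasons


def aggregate(
    percent: pd.DataFrame,
    gene: GeneModel,
    rule: str = "downstream_cutoff",
    cutoff: int = 50,
    region: str | None = None,
) -> pd.Series:
    """Unweighted mean percent remaining over qualifying unmasked sites.

    ``downstream_cutoff`` qualifies sites strictly beyond +``cutoff``
    (TSS-relative; +50 itself excluded by default); ``nucleosome_region``
    qualifies sites inside intervals labelled ``region`` ("core"|"linker").
    """
    sites = percent.index.to_numpy()
    if rule == "downstream_cutoff":
        qual = sites > cutoff
    elif rule == "nucleosome_region":
        if region not in ("core", "linker"):
            raise ValueError("nucleosome_region rule needs region='core'|'linker'")
        qual = np.array([gene.region_at(int(s)) == region for s in sites])
    else:
        raise ValueError(f"unknown aggregation rule {rule!r}")
    sub = percent.loc[qual]
    means = sub.mean(axis=0, skipna=True)
    if sub.dropna(how="all").empty:
        warnings.warn(f"{gene.name}: no qualifying unmasked sites under {rule}")
    return means


def paired_t_test(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Classical paired Student's t per timepoint, pairing over genes.

    ``a`` and ``b`` are gene x timepoint aggregate tables.  Returns per
    timepoint: t, df (= n-1), two-sided p, and significance stars (p < 0.01:
    '**', p < 0.05: '*').  All-zero differences give t = 0, p = 1 (declared
    convention); fewer than 2 complete pairs is an error.
    """
    common_t = [c for c in a.columns if c in b.columns]
    rows = []
    for t in common_t:
        pair = pd.concat([a[t], b[t]], axis=1, keys=["a", "b"]).dropna()
        n = len(pair)
        if n < 2:
            raise ValueError(f"timepoint {t}: fewer than 2 complete pairs")
        diff = pair["a"] - pair["b"]
        if np.allclose(diff, 0):
            tstat, p = 0.0, 1.0
        else:
            tstat, p = stats.ttest_rel(pair["a"], pair["b"])
        stars = "**" if p < 0.01 else ("*" if p < 0.05 else "")
        rows.append((t, float(tstat), n - 1, float(p), stars))
    return pd.DataFrame(rows, columns=["timepoint", "t", "df", "p", "stars"])


@dataclass(frozen=True)
class TcrLevelRule:
    """Ordinal TCR-enhancement level rule.

    ``cutoffs`` are (level, minimum mean reduction in percentage points)
    pairs in decreasing level order; a comparison reaching none of them is
    level 0.  ``timepoints`` are the repair times (hours) entering the mean.
    """

    name: str
    timepoints: tuple[float, ...]
    cutoffs: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        levels = [l for l, _ in self.cutoffs]
        cuts = [c for _, c in self.cutoffs]
        if levels != sorted(levels, reverse=True) or cuts != sorted(cuts, reverse=True):
            raise ValueError("cutoffs must decrease with level")
        if levels != list(range(levels[0], 0, -1)):
            raise ValueError("levels must be contiguous down to 1")


THREE_TIMEPOINT = TcrLevelRule("three_timepoint", (0.5, 1.0, 3.0),
                               ((3, 30.0), (2, 20.0), (1, 10.0)))
TWO_TIMEPOINT = TcrLevelRule("two_timepoint", (0.5, 1.0),
                             ((2, 20.0), (1, 10.0)))
RULESETS = {r.name: r for r in (THREE_TIMEPOINT, TWO_TIMEPOINT)}


def classify_tcr_level(
    wildtype: pd.DataFrame,
    mutant: pd.DataFrame,
    rule: TcrLevelRule = THREE_TIMEPOINT,
) -> int:
    """TCR-enhancement level from wild-type vs mutant aggregate tables.

    The reduction is the mean over (genes x rule timepoints) of wild-type
    minus mutant percent remaining, in percentage points; the call is the
    highest level whose cutoff the reduction reaches, else 0.
    """
    from .simulate import sample_name

    cols = [sample_name(t) for t in rule.timepoints]
    missing = []
    for df, lab in ((wildtype, "wildtype"), (mutant, "mutant")):
        for c in cols:
            if c not in df.columns:
                missing.extend((lab, g, c) for g in df.index)
            else:
                for g in df.index[df[c].isna()]:
                    missing.append((lab, g, c))
    if missing:
        raise ValueError(f"missing aggregate cells: {missing}")
    if not wildtype.index.equals(mutant.index):
        mutant = mutant.reindex(wildtype.index)
        if mutant.isna().any().any():
            raise ValueError("wildtype and mutant cover different genes")
    reduction = float((wildtype[cols] - mutant[cols]).to_numpy().mean())
    for level, cut in rule.cutoffs:
        if reduction >= cut:
            return level
    return 0


class RepairKinetics:
    """Repair-kinetics model over per-gene, per-strand lesion count tables.

    Parameters
    ----------
    tables
        Mapping ``(gene name, strand)`` -> :class:`LesionCountTable`; samples
        must include the unirradiated control and the time-0 sample.
    genes
        Mapping gene name -> :class:`GeneModel` (for coordinates/regions).
    strand
        Which strand to quantify ("TS" for transcription-coupled repair,
        "NTS" for global-genomic repair).
    """

    def __init__(
        self,
        tables: Mapping[tuple[str, str], LesionCountTable],
        genes: Mapping[str, GeneModel],
        strand: str = "TS",
        control: str = "U",
        t0: str = "0h",
        min_t0: float = 5.0,
        cutoff: int = 50,
    ):
        self.tables = dict(tables)
        self.genes = dict(genes)
        self.strand = strand
        self.control = control
        self.t0 = t0
        self.min_t0 = min_t0
        self.cutoff = cutoff

    def fit(self, rule: str = "downstream_cutoff",
            region: str | None = None) -> "RepairResults":
        per_site = {}
        masks = {}
        agg_rows = {}
        for (gname, strand), table in self.tables.items():
            if strand != self.strand:
                continue
            adjusted = normalize_and_subtract(table, self.control)
            pct, reasons = percent_remaining(adjusted, self.t0, self.min_t0)
            per_site[gname] = pct
            masks[gname] = reasons
            agg_rows[gname] = aggregate(pct, self.genes[gname], rule,
                                        self.cutoff, region)
        if not per_site:
            raise ValueError(f"no tables for strand {self.strand!r}")
        aggregates = pd.DataFrame(agg_rows).T
        aggregates.index.name = "gene"
        return RepairResults(self, per_site, masks, aggregates, rule, region)


@dataclass
class RepairResults:
    """Per-site and aggregated percent-CPDs-remaining for one genotype."""

    model: RepairKinetics
    per_site: dict[str, pd.DataFrame] = field(repr=False)
    masks: dict[str, pd.Series] = field(repr=False)
    aggregates: pd.DataFrame
    rule: str
    region: str | None

    def paired_t(self, other: "RepairResults") -> pd.DataFrame:
        """Paired t test of this genotype vs another, pairing over genes."""
        return paired_t_test(self.aggregates, other.aggregates)

    def tcr_level(self, mutant: "RepairResults",
                  rule: TcrLevelRule = THREE_TIMEPOINT) -> int:
        """Treat self as wild type and classify the mutant's enhancement."""
        return classify_tcr_level(self.aggregates, mutant.aggregates, rule)

    def per_site_table(self) -> pd.DataFrame:
        rows = []
        for gname, pct in self.per_site.items():
            reasons = self.masks[gname]
            for site in pct.index:
                for t in pct.columns:
                    rows.append((gname, self.model.strand, int(site), t,
                                 pct.loc[site, t], reasons.loc[site]))
        return pd.DataFrame(rows, columns=["gene", "strand", "site",
                                           "timepoint", "percent_remaining",
                                           "mask_reason"])

    def summary(self) -> str:
        lines = [
            f"Percent CPDs remaining ({self.model.strand}; rule={self.rule}"
            + (f", region={self.region}" if self.region else
               f", cutoff=+{self.model.cutoff}") + ")",
            "=" * 60,
            self.aggregates.to_string(float_format=lambda x: f"{x:.1f}"),
        ]
        return "\n".join(lines)
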