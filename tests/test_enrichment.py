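"""Coverage arithmetic, normalization, batch centering and the M/D/theta
probability statistic."""

import numpy as np
import pandas as pd
import pytest

from repairscreen.enrichment import (
    ScreenEnrichment,
    compute_enrichment,
    correct_batches,
    coverage_summary,
    filter_hits,
    normalize_counts,
)
from repairscreen.screen_reads import AMINO_ACIDS, CodonCountMatrix


def matrix_with_covered(n_covered: int, count: int = 3) -> CodonCountMatrix:
    """A count matrix in which exactly ``n_covered`` (position, aa) variants
    have nonzero pooled counts."""
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
    return CodonCountMatrix(counts=counts,
                            depths=pd.Series({"UV_r1": 10_000}))


class TestCoverage:
    @pytest.mark.parametrize("covered, pct", [
        (3344, 98.4),   # the printed screen coverage arithmetic
        (0, 0.0),
        (3400, 100.0),
    ])
    def test_percent_of_3400_variant_space(self, covered, pct):
        got_n, got_pct = coverage_summary(matrix_with_covered(covered))
        assert got_n == covered
        assert got_pct == pct

    def test_min_count_threshold_applies(self):
        m = matrix_with_covered(10, count=1)
        assert coverage_summary(m, min_count=2)[0] == 0


def small_matrix(counts_by_sample):
    rows = []
    for sample, cnts in counts_by_sample.items():
        for (pos, aa), n in cnts.items():
            rows.append((pos, "NNN", aa, sample, n))
    depths = {s: sum(c.values()) or 1 for s, c in counts_by_sample.items()}
    return CodonCountMatrix(
        counts=pd.DataFrame(rows, columns=["position", "codon", "aa",
                                           "sample", "count"]),
        depths=pd.Series(depths))


class TestNormalize:
    def test_pseudocount_formula(self):
        m = small_matrix({"UV_r1": {(5, "A"): 0}})
        m.depths = pd.Series({"UV_r1": 1_000_000})
        ab = normalize_counts(m, pseudocount=0.5)
        assert ab.loc[(5, "A"), "UV_r1"] == pytest.approx(0.5)

    def test_doubling_depth_halves_abundance(self):
        m = small_matrix({"UV_r1": {(5, "A"): 100}})
        m.depths = pd.Series({"UV_r1": 10_000})
        a1 = normalize_counts(m).loc[(5, "A"), "UV_r1"]
        m.depths = pd.Series({"UV_r1": 20_000})
        a2 = normalize_counts(m).loc[(5, "A"), "UV_r1"]
        assert a1 == pytest.approx(2 * a2)

    def test_zero_depth_rejected(self):
        m = small_matrix({"UV_r1": {(5, "A"): 1}})
        m.depths = pd.Series({"UV_r1": 0})
        with pytest.raises(ValueError, match="depth"):
            normalize_counts(m)


class TestBatchCorrection:
    def rand_table(self, seed=0, n=200, cols=3):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.lognormal(3, 1, size=(n, cols)),
                            columns=[f"UV_r{i}" for i in range(cols)])

    def test_identical_replicates_unchanged(self):
        t = self.rand_table()
        t["UV_r1"] = t["UV_r0"]
        t["UV_r2"] = t["UV_r0"]
        out = correct_batches(t)
        assert np.allclose(out, t)

    def test_global_scale_factor_removed(self):
        # scaling one replicate x2 then correcting equals correcting the
        # original table up to one global constant: all between-sample ratios
        # are restored
        t = self.rand_table()
        t2 = t.copy()
        t2["UV_r1"] = t2["UV_r1"] * 2.0
        out, out2 = correct_batches(t), correct_batches(t2)
        rel = (out2 / out).to_numpy()
        assert np.allclose(rel, rel[0, 0], rtol=1e-9)

    def test_idempotent(self):
        t = self.rand_table(seed=5)
        once = correct_batches(t)
        twice = correct_batches(once)
        assert np.allclose(once, twice, rtol=1e-9, atol=1e-9)

    def test_single_sample_warns_identity(self):
        t = self.rand_table()[["UV_r0"]]
        with pytest.warns(UserWarning):
            out = correct_batches(t)
        assert out.equals(t)


def abundances(mu_uv, mu_ctrl, noise, n=50, seed=0):
    """Two-condition, 3-replicate table with one focal variant on top of a
    noisy background."""
    rng = np.random.default_rng(seed)
    base = rng.lognormal(4, 0.5, size=n)
    df = {}
    for cond, mu in (("UV", mu_uv), ("noUV", mu_ctrl)):
        for r in range(1, 4):
            col = base * np.exp(rng.normal(0, noise, size=n))
            col[0] = mu * np.exp(rng.normal(0, noise))
            df[f"{cond}_r{r}"] = col
    idx = pd.MultiIndex.from_tuples([(i + 2, "A") for i in range(n)],
                                    names=["position", "aa"])
    return pd.DataFrame(df, index=idx)


class TestComputeEnrichment:
    def test_log2fc_of_count_400_over_100_with_pseudocount(self):
        m = small_matrix({f"{c}_r{r}": {(5, "A"): n, (6, "C"): 10}
                          for c, n in (("UV", 400), ("noUV", 100))
                          for r in (1, 2)})
        for s in m.depths.index:
            m.depths[s] = 1_000_000
        ab = normalize_counts(m, pseudocount=0.5)
        table = compute_enrichment(ab)
        M = table.loc[(5, "A"), "M"]
        assert M == pytest.approx(np.log2(400.5 / 100.5), abs=1e-12)
        assert M == pytest.approx(1.994, abs=1e-3)

    def test_theta_is_mean_of_m_and_d(self):
        ab = abundances(400.0, 100.0, noise=0.05)
        table = compute_enrichment(ab)
        assert np.allclose(table["theta"], (table["M"] + table["D"]) / 2)

    def test_equal_means_give_zero_probability(self):
        # identical replicate values within and across conditions: the focal
        # contrast (M=0, D=0) strictly dominates no noise pair
        idx = pd.MultiIndex.from_tuples([(2, "A"), (3, "C")])
        ab = pd.DataFrame({f"{c}_r{r}": [100.0, 50.0] for c in ("UV", "noUV")
                           for r in (1, 2, 3)}, index=idx)
        table = compute_enrichment(ab)
        assert (table["M"] == 0).all()
        assert (table["probability"] == 0).all()

    def test_swapping_condition_labels_negates_m(self):
        ab = abundances(300.0, 80.0, noise=0.1)
        t1 = compute_enrichment(ab)
        swap = {s: s.replace("UV", "XX").replace("noXX", "UV").replace("XX", "noUV")
                for s in ab.columns}
        t2 = compute_enrichment(ab.rename(columns=swap)).reindex(t1.index)
        assert np.allclose(t1["M"], -t2["M"])
        assert np.allclose(t1["D"], t2["D"])

    def test_strong_signal_earns_high_probability(self):
        ab = abundances(1000.0, 100.0, noise=0.05)
        table = compute_enrichment(ab)
        assert table.loc[(2, "A"), "probability"] > 0.98
        assert table.index[0] == (2, "A")  # sorted by theta, top hit first

    def test_requires_two_replicates_per_condition(self):
        ab = abundances(100.0, 100.0, noise=0.05)
        with pytest.raises(ValueError):
            compute_enrichment(ab[["UV_r1", "noUV_r1", "noUV_r2"]])


class TestFilterHits:
    def table(self, rows):
        idx = pd.MultiIndex.from_tuples([r[0] for r in rows],
                                        names=["position", "aa"])
        df = pd.DataFrame([r[1] for r in rows], index=idx,
                          columns=["M", "probability"])
        df["D"] = np.abs(df["M"]) * 2
        df["theta"] = (df["M"] + df["D"]) / 2
        return df

    def test_strict_thresholds(self):
        t = self.table([
            ((149, "D"), (2.78, 1.0)),     # clear hit
            ((10, "A"), (1.0, 1.0)),       # M not strictly > 1
            ((11, "C"), (1.5, 0.9)),       # probability too low
            ((12, "E"), (1.2, 0.98)),      # probability not strictly > 0.98
            ((13, "F"), (-2.0, 0.99)),     # depleted
        ])
        hits, depleted = filter_hits(t)
        assert list(hits.index) == [(149, "D")]
        assert list(depleted.index) == [(13, "F")]

    def test_hits_sorted_by_theta_descending(self):
        t = self.table([((2, "A"), (1.5, 1.0)), ((3, "C"), (3.0, 1.0))])
        hits, _ = filter_hits(t)
        assert list(hits["theta"]) == sorted(hits["theta"], reverse=True)


def test_model_results_round_trip():
    """ScreenEnrichment.fit returns a results object whose table obeys the
    hit rule and whose summary renders."""
    rng = np.random.default_rng(2)
    counts = {}
    for c in ("UV", "noUV"):
        for r in (1, 2, 3):
            cnts = {(pos, "A"): int(rng.poisson(50)) for pos in range(2, 30)}
            if c == "UV":
                cnts[(149, "D")] = 400
            else:
                cnts[(149, "D")] = 60
            counts[f"{c}_r{r}"] = cnts
    m = small_matrix(counts)
    res = ScreenEnrichment(m).fit()
    assert ((res.table["hit"]) == ((res.table["M"] > 1)
                                   & (res.table["probability"] > 0.98))).all()
    assert (149, "D") in res.hits().index
    assert "theta" in res.summary()
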