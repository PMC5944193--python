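import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import ttsakit as tk
from ttsakit.errors import DegenerateTableError, InsufficientDataError, UsageError
from ttsakit.stats import top_enriched

from oracles import (fisher_two_sided_enum, hypergeom_upper_enum,
                     rank_sum_two_sided_enum, signed_rank_two_sided_enum)

# human TTSa-RNAs validated by qRT-PCR; none starts with G
QPCR_PANEL = [
    "CTAATAAACGAGATGCAGAACCCT",   # BUB3
    "CATATTAAAAGTCACTCTGAGCT",    # WEE1
    "TTTATTAAAAGAGAAACCTGAAG",    # PSMB1
    "CTCAATAAATGATTCTTAGTGACT",   # CDKNA1
    "CAGTGACGAGGAACTCCCGAGA",     # YWHAG
]


class TestComposition:
    def test_positional_counting(self):
        c = tk.composition(["AA", "AC"])
        assert c.freqs.loc[1, "A"] == 1.0
        assert c.freqs.loc[2, "A"] == 0.5 and c.freqs.loc[2, "C"] == 0.5
        assert c.first_nt == {"A": 1.0, "C": 0.0, "G": 0.0, "T": 0.0}

    def test_rows_sum_to_one_over_covering_reads(self):
        c = tk.composition(["ACGT", "AC", "ACG"])
        sums = c.freqs.sum(axis=1)
        assert np.allclose(sums, 1.0)
        assert list(c.n) == [3, 3, 2, 1]

    def test_qpcr_panel_has_no_first_position_g(self):
        c = tk.composition(QPCR_PANEL)
        assert c.first_nt_counts["G"] == 0
        assert sum(c.first_nt_counts.values()) == 5

    def test_empty_rejected(self):
        with pytest.raises(UsageError):
            tk.composition([])


class TestGBias:
    def test_extreme_table_in_log_space(self):
        res = tk.g_bias_test({"G": 0, "A": 100}, {"G": 100, "A": 0})
        expected = fisher_two_sided_enum([[0, 100], [100, 0]])
        assert res.pvalue == pytest.approx(expected, rel=1e-9)
        assert res.log10_pvalue == pytest.approx(np.log10(expected), rel=1e-9)

    def test_equal_fractions_null(self):
        res = tk.g_bias_test({"G": 10, "A": 90}, {"G": 20, "A": 180})
        assert res.odds_ratio == pytest.approx(1.0) and res.pvalue == pytest.approx(1.0)

    def test_matches_enumeration(self, rng):
        for _ in range(60):
            a, b, c, d = (int(x) for x in rng.integers(0, 13, 4))
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            res = tk.fisher_exact_2x2([[a, b], [c, d]])
            assert res.pvalue == pytest.approx(
                fisher_two_sided_enum([[a, b], [c, d]]), rel=1e-9, abs=1e-15)

    def test_power_at_reported_rates(self):
        # 3.25% vs 8.10% first-position G at 50k reads per group
        n = 50_000
        res = tk.g_bias_test({"G": int(0.0325 * n), "A": n - int(0.0325 * n)},
                             {"G": int(0.0810 * n), "A": n - int(0.0810 * n)})
        assert res.log10_pvalue < np.log10(2.2e-16)

    def test_underflow_keeps_log_pvalue(self):
        res = tk.g_bias_test({"G": 10, "A": 500_000}, {"G": 4000, "A": 46_000})
        assert res.pvalue < 2.2e-16
        assert np.isfinite(res.log10_pvalue) and res.log10_pvalue < -100

    def test_degenerate_margin(self):
        with pytest.raises(DegenerateTableError):
            tk.fisher_exact_2x2([[0, 5], [0, 5]])


class TestCorrelateExpression:
    def frame(self, values, samples=("s1",)):
        return pd.DataFrame({s: values for s in samples},
                            index=[f"g{i}" for i in range(len(values))])

    def test_perfectly_monotone(self):
        x = self.frame(np.arange(40.0) + 1)
        y = self.frame(np.arange(40.0) ** 2 + 1)
        res = tk.correlate_expression(x, y)
        assert res["spearman_rho"] == pytest.approx(1.0)
        assert res["r_squared"] == pytest.approx(1.0)

    def test_anti_monotone(self):
        x = self.frame(np.arange(40.0) + 1)
        y = self.frame(-np.arange(40.0))
        res = tk.correlate_expression(x, y, ttsa_quartile_filter=False)
        assert res["spearman_rho"] == pytest.approx(-1.0)
        assert res["r_squared"] == pytest.approx(1.0)

    def test_monotone_transform_invariance(self, rng):
        x = self.frame(rng.lognormal(2, 1, 200))
        y = self.frame(rng.lognormal(1, 1, 200))
        r1 = tk.correlate_expression(x, y)
        r2 = tk.correlate_expression(np.log1p(x), y ** 3)
        assert r1["spearman_rho"] == pytest.approx(r2["spearman_rho"])

    def test_filters_reduce_n(self, rng):
        x = self.frame(rng.lognormal(2, 1, 300))
        y = self.frame(rng.lognormal(1, 1, 300))
        res = tk.correlate_expression(x, y)
        # tertile filter keeps ~200 genes, quartile filter keeps the top 25%
        assert res["n"] == pytest.approx(50, abs=2)

    def test_independent_data_low_r_squared(self, rng):
        x = self.frame(rng.lognormal(2, 1, 3200))
        y = self.frame(rng.lognormal(1, 1.5, 3200))
        res = tk.correlate_expression(x, y)
        assert res["n"] >= 500
        assert res["r_squared"] < 0.1

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            tk.correlate_expression(self.frame([1.0, 2.0]), self.frame([1.0, 2.0]))


class TestCompareCohorts:
    def table(self, tumor, control, paired=True):
        rows = []
        for i, v in enumerate(tumor):
            rows.append((f"t{i}", "tumor", f"p{i}" if paired else None, v))
        for i, v in enumerate(control):
            rows.append((f"c{i}", "control", f"p{i}" if paired else None, v))
        return pd.DataFrame(rows, columns=["sample", "condition", "pair_id", "ttsa_rpm"])

    def test_six_concordant_pairs(self):
        t = [10.0, 20, 30, 40, 50, 60]
        c = [9.0, 17, 26, 34, 43, 51]  # all tumor > control, distinct |diffs|
        res = tk.compare_cohorts(self.table(t, c))
        assert res.paired and res.pvalue == pytest.approx(2 / 64)

    def test_paired_matches_enumeration(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 9))
            t = rng.normal(1, 2, n).round(3)
            c = rng.normal(0, 2, n).round(3)
            d = t - c
            if np.any(d == 0) or len(np.unique(np.abs(d))) < n:
                continue
            res = tk.compare_cohorts(self.table(list(t), list(c)))
            assert res.pvalue == pytest.approx(signed_rank_two_sided_enum(d))

    def test_unpaired_matches_enumeration(self, rng):
        for _ in range(25):
            n1, n2 = int(rng.integers(3, 7)), int(rng.integers(3, 7))
            t = rng.normal(1, 2, n1).round(3)
            c = rng.normal(0, 2, n2).round(3)
            if len(np.unique(np.concatenate([t, c]))) < n1 + n2:
                continue
            res = tk.compare_cohorts(self.table(list(t), list(c), paired=False),
                                     paired=False)
            assert res.test == "wilcoxon_rank_sum"
            assert res.pvalue == pytest.approx(rank_sum_two_sided_enum(t, c))

    def test_identical_groups_p_one(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = tk.compare_cohorts(self.table([5.0, 5, 5], [5.0, 5, 5]))
        assert res.pvalue == 1.0

    def test_paired_shift_invariance(self):
        t = [10.0, 20, 35, 41, 52]
        c = [8.0, 25, 30, 44, 50]
        p1 = tk.compare_cohorts(self.table(t, c)).pvalue
        p2 = tk.compare_cohorts(self.table([x + 100 for x in t],
                                           [x + 100 for x in c])).pvalue
        assert p1 == p2

    def test_pairing_must_be_bijective(self):
        df = self.table([1.0, 2], [3.0, 4])
        df.loc[df["sample"] == "c1", "pair_id"] = "p0"
        with pytest.raises(UsageError):
            tk.compare_cohorts(df)

    def test_fold_change_table(self):
        df = self.table([10.0, 20], [5.0, 8])
        mat = pd.DataFrame({"siteA": [10, 20, 5, 8], "siteB": [2, 2, 2, 2]},
                           index=["t0", "t1", "c0", "c1"], dtype=float)
        res = tk.compare_cohorts(df, site_matrix=mat)
        assert res.fold_change.loc["siteA", "fold_change"] == pytest.approx(15 / 6.5)
        assert res.fold_change.loc["siteB", "fold_change"] == pytest.approx(1.0)


class TestEnrichment:
    def test_enumeration_example(self):
        bg = [f"g{i}" for i in range(100)]
        hits = set(bg[:10])
        sets = {"S": set(bg[:5]) | set(bg[50:55])}  # K=10, k=5
        table = tk.enrich_gene_sets(hits, bg, sets)
        assert table.loc[0, "p"] == pytest.approx(hypergeom_upper_enum(5, 100, 10, 10))
        assert table.loc[0, "fold_enrichment"] == pytest.approx((5 / 10) / (10 / 100))

    def test_whole_set_hit_fold(self):
        bg = [f"g{i}" for i in range(100)]
        table = tk.enrich_gene_sets(set(bg[:10]), bg, {"S": bg[:10]})
        assert table.loc[0, "fold_enrichment"] == pytest.approx(10.0)

    def test_random_hits_rarely_significant(self, rng):
        bg = [f"g{i}" for i in range(400)]
        sets = {f"S{j}": list(rng.choice(bg, size=25, replace=False))
                for j in range(30)}
        n_signif = 0
        for _ in range(40):
            hits = set(rng.choice(bg, size=30, replace=False))
            table = tk.enrich_gene_sets(hits, bg, sets)
            n_signif += int(table["significant"].any())
        assert n_signif <= 2  # FDR 0.01: >95% of random draws yield nothing

    def test_hits_outside_background_rejected(self):
        with pytest.raises(UsageError):
            tk.enrich_gene_sets({"x"}, {"a", "b"}, {})

    def test_empty_hits(self):
        assert tk.enrich_gene_sets(set(), {"a"}, {"S": ["a"]}).empty

    def test_top_view_keeps_significant_by_fold(self, rng):
        bg = [f"g{i}" for i in range(200)]
        sets = {"big": bg[:50], "small": bg[:5]}
        hits = set(bg[:20])
        table = tk.enrich_gene_sets(hits, bg, sets)
        top = top_enriched(table, 10)
        assert (top["q"] < 0.01).all()
        assert list(top["fold_enrichment"]) == sorted(top["fold_enrichment"], reverse=True)

    def test_q_values_monotone_in_ranked_p(self, rng):
        bg = [f"g{i}" for i in range(300)]
        sets = {f"S{j}": list(rng.choice(bg, size=int(rng.integers(5, 60)),
                                         replace=False)) for j in range(25)}
        hits = set(rng.choice(bg, size=40, replace=False)) | set(sets["S0"][:10])
        table = tk.enrich_gene_sets(hits & set(bg), bg, sets).sort_values("p")
        assert np.all(np.diff(table["q"].to_numpy()) >= -1e-12)
        assert ((table["p"] > 0) & (table["p"] <= 1)).all()
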