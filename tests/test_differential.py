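"""Negative-binomial differential expression: size factors, dispersion,
Wald test, Cook's flags, independent filtering, BH, thresholds, pooling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from meiochrom.differential import (
    ALPHA_FLOOR,
    bh_adjust,
    call_significant,
    cooks_distances,
    cooks_outlier_flags,
    estimate_dispersion,
    independent_filter,
    pooled_pirna_test,
    run_de_pipeline,
    size_factors,
    wald_test,
    DEResult,
)
from meiochrom.quantify import CountTable, make_sample_sheet
from meiochrom.simulate import simulate_count_table

CONTRAST = ("condition", "KO", "WT")


def sheet(names, conds):
    return make_sample_sheet(
        {
            "sample": n,
            "condition": c,
            "stage": "meiotic",
            "assay": "rnaseq",
            "library_size": 1_000_000,
        }
        for n, c in zip(names, conds)
    )


def table(counts: dict, index, n_per_group=None):
    names = list(counts)
    conds = ["WT"] * (len(names) // 2) + ["KO"] * (len(names) - len(names) // 2)
    return CountTable(pd.DataFrame(counts, index=index), sheet(names, conds))


class TestSizeFactors:
    def test_hand_worked_two_sample_table(self):
        df = pd.DataFrame({"s1": [2, 2], "s2": [8, 8]})
        assert np.allclose(size_factors(df).values, [0.5, 2.0], atol=1e-12)

    def test_identical_columns_give_unit_factors(self):
        df = pd.DataFrame({"s1": [5, 9, 2], "s2": [5, 9, 2], "s3": [5, 9, 2]})
        assert np.allclose(size_factors(df).values, [1, 1, 1], atol=1e-12)

    def test_zero_count_feature_excluded(self):
        # gene 1 has a zero -> excluded; medians of (1,3) and (1,1/3)
        df = pd.DataFrame({"s1": [0, 4, 9], "s2": [5, 4, 1]})
        assert np.allclose(size_factors(df).values, [2.0, 2.0 / 3.0], atol=1e-12)

    def test_all_features_with_zeros_rejected(self):
        df = pd.DataFrame({"s1": [0, 4], "s2": [5, 0]})
        with pytest.raises(ValueError):
            size_factors(df)

    def test_scale_invariance(self):
        """Multiplying one sample by c multiplies its size factor by c and
        leaves log2FC estimates unchanged at zero dispersion."""
        rng = np.random.default_rng(3)
        q = rng.integers(10, 1000, size=300)
        counts = pd.DataFrame(
            {"WT_rep1": q, "WT_rep2": q, "KO_rep1": 2 * q, "KO_rep2": 2 * q}
        )
        tab = CountTable(counts, sheet(counts.columns, ["WT", "WT", "KO", "KO"]))
        sf1 = size_factors(tab.counts)
        scaled = tab.counts.copy()
        scaled["KO_rep1"] = scaled["KO_rep1"] * 4
        tab2 = CountTable(scaled, tab.samples)
        sf2 = size_factors(tab2.counts)
        # size factors are defined up to a common constant: the scaled
        # sample's factor rises by c relative to every other sample
        rel = (sf2["KO_rep1"] / sf1["KO_rep1"]) / (sf2["WT_rep1"] / sf1["WT_rep1"])
        assert np.allclose(rel, 4.0, rtol=1e-12)
        disp1 = estimate_dispersion(tab, sf1, CONTRAST)
        disp1.alpha[:] = ALPHA_FLOOR
        r1, _ = wald_test(tab, sf1, disp1, CONTRAST)
        r2, _ = wald_test(tab2, sf2, disp1, CONTRAST)
        assert np.allclose(
            r1.table["log2FoldChange"], r2.table["log2FoldChange"], atol=1e-6
        )


class TestDispersion:
    def test_poisson_counts_yield_near_zero_dispersion(self):
        tab, _ = simulate_count_table(400, 0.0, 0.0, 4, seed=9)
        sf = size_factors(tab.counts)
        disp = estimate_dispersion(tab, sf, CONTRAST)
        assert np.nanmedian(disp.alpha_mle) < 0.05

    def test_nb_dispersion_recovered(self):
        tab, _ = simulate_count_table(
            400, 0.0, 0.5, 4, mean_log=np.log(2000), mean_sd=0.3, seed=10
        )
        sf = size_factors(tab.counts)
        disp = estimate_dispersion(tab, sf, CONTRAST)
        med = float(np.nanmedian(disp.alpha))
        assert 0.25 < med < 0.75  # within +-50% of the true value
        frac_close = np.mean(np.abs(np.log(disp.alpha.dropna() / 0.5)) < np.log(2.0))
        assert frac_close > 0.9

    def test_constant_feature_hits_floor(self):
        counts = pd.DataFrame(
            {f"s{j}": [100, 200] for j in range(8)},
            index=["flat", "flat2"],
        )
        tab = CountTable(counts, sheet(counts.columns, ["WT"] * 4 + ["KO"] * 4))
        disp = estimate_dispersion(tab, size_factors(counts), CONTRAST)
        assert (disp.alpha_mle < 1e-6).all()

    def test_all_zero_feature_flagged(self):
        counts = pd.DataFrame(
            {"s1": [0, 5], "s2": [0, 6], "s3": [0, 7], "s4": [0, 8]}, index=["z", "ok"]
        )
        tab = CountTable(counts, sheet(counts.columns, ["WT", "WT", "KO", "KO"]))
        disp = estimate_dispersion(tab, pd.Series(1.0, index=counts.columns), CONTRAST)
        assert disp.all_zero["z"] and not disp.all_zero["ok"]
        assert np.isnan(disp.alpha["z"])


class TestWaldTest:
    def test_null_pvalues_uniform(self):
        tab, _ = simulate_count_table(2000, 0.0, 0.05, 2, seed=21)
        res = run_de_pipeline(tab, CONTRAST, independent_filtering=False)
        pv = res.table["pvalue"].dropna()
        assert sps.kstest(pv, "uniform").pvalue > 0.001

    def test_closed_form_limit_at_zero_dispersion(self):
        # group means 100 vs 400, no noise -> beta_hat -> log2(4) = 2
        counts = pd.DataFrame(
            {f"w{j}": [100] for j in range(4)} | {f"k{j}": [400] for j in range(4)},
            index=["g"],
        )
        tab = CountTable(counts, sheet(counts.columns, ["WT"] * 4 + ["KO"] * 4))
        sf = pd.Series(1.0, index=counts.columns)
        disp = estimate_dispersion(tab, sf, CONTRAST)
        disp.alpha[:] = ALPHA_FLOOR
        res, _ = wald_test(tab, sf, disp, CONTRAST)
        assert res.table["log2FoldChange"]["g"] == pytest.approx(2.0, abs=1e-6)

    def test_planted_sign_recovery(self):
        lfc = np.where(np.arange(500) < 250, 3.32, -3.32)
        tab, _ = simulate_count_table(
            500, lfc, 0.05, 2, mean_log=np.log(500), mean_sd=0.5, seed=31
        )
        res = run_de_pipeline(tab, CONTRAST, independent_filtering=False)
        sign_ok = np.sign(res.table["log2FoldChange"]) == np.sign(lfc)
        assert sign_ok.mean() >= 0.99

    def test_lfc_bias_small_at_high_counts(self):
        lfc = np.repeat([1.0, -1.0], 200)
        tab, _ = simulate_count_table(
            400, lfc, 0.05, 4, mean_log=np.log(2000), mean_sd=0.2, seed=41
        )
        res = run_de_pipeline(tab, CONTRAST, independent_filtering=False)
        bias = (res.table["log2FoldChange"].to_numpy() - lfc).mean()
        assert abs(bias) < 0.1


class TestCooks:
    def test_gross_outlier_flagged_with_four_replicates(self):
        # (10, 11, 9, 1000) in one group, embedded in a well-behaved
        # background so the dispersion trend reflects typical genes
        tab, _ = simulate_count_table(300, 0.0, 0.05, 4, seed=55)
        counts = tab.counts.copy()
        counts.iloc[0] = [10, 11, 9, 1000, 10, 12, 11, 9]
        tab = CountTable(counts, tab.samples)
        sf = pd.Series(1.0, index=counts.columns)
        disp = estimate_dispersion(tab, sf, CONTRAST)
        _, fit = wald_test(tab, sf, disp, CONTRAST)
        trend = disp.trend.to_numpy(dtype=float)
        d = cooks_distances(fit, counts.to_numpy(dtype=float), alpha=trend)
        assert d[0].argmax() == 3  # the 1000 count dominates
        flags = cooks_outlier_flags(fit, counts.to_numpy(dtype=float), alpha=trend)
        assert flags[0]
        # a hand computation of Cook's D for the outlying sample agrees
        mu, a, x = fit.mu[0], trend[0], fit.x
        w = mu / (1 + a * mu)
        X = np.column_stack([np.ones_like(x), x])
        H = np.diag(np.sqrt(w)) @ X @ np.linalg.inv(X.T @ (w[:, None] * X)) @ X.T @ np.diag(np.sqrt(w))
        h = np.diag(H)
        r2 = (counts.iloc[0].to_numpy() - mu) ** 2 / (mu + a * mu**2)
        d_hand = r2 / 2 * h / (1 - h) ** 2
        assert np.allclose(d[0], d_hand, rtol=1e-8)

    def test_disabled_on_two_replicate_design(self):
        tab, _ = simulate_count_table(50, 0.0, 0.05, 2, seed=51)
        sf = size_factors(tab.counts)
        disp = estimate_dispersion(tab, sf, CONTRAST)
        _, fit = wald_test(tab, sf, disp, CONTRAST)
        assert not cooks_outlier_flags(fit, tab.counts.to_numpy(dtype=float)).any()

    def test_null_flag_rate_low(self):
        tab, _ = simulate_count_table(1000, 0.0, 0.05, 4, seed=61)
        sf = size_factors(tab.counts)
        disp = estimate_dispersion(tab, sf, CONTRAST)
        _, fit = wald_test(tab, sf, disp, CONTRAST)
        flags = cooks_outlier_flags(fit, tab.counts.to_numpy(dtype=float))
        assert flags.mean() < 0.02


class TestBH:
    def test_hand_worked_example(self):
        assert np.allclose(bh_adjust([0.01, 0.04, 0.03]), [0.03, 0.04, 0.04], atol=1e-12)

    def test_single_and_degenerate(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_missing_excluded_from_m(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        assert np.allclose(out[[0, 2]], [0.02, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_matches_independent_reference(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 200))
            ours = bh_adjust(p)
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(ours, ref, atol=1e-12)

    def test_monotone_and_order_invariant(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=500)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        perm = rng.permutation(500)
        assert np.allclose(bh_adjust(p[perm]), adj[perm], atol=1e-15)


class TestIndependentFilter:
    def make_result(self, base, p):
        df = pd.DataFrame(
            {
                "baseMean": base,
                "log2FoldChange": 0.0,
                "lfcSE": 1.0,
                "stat": 0.0,
                "pvalue": p,
                "padj": np.nan,
                "cooks_outlier": False,
                "independent_filtered": False,
                "significant": False,
                "direction": "",
            },
            index=[f"f{i}" for i in range(len(base))],
        )
        return DEResult(df)

    def test_filter_never_loses_rejections(self):
        rng = np.random.default_rng(2)
        base = np.concatenate([rng.uniform(0, 5, 500), rng.uniform(500, 1000, 100)])
        p = np.concatenate([rng.uniform(size=500), rng.uniform(0, 1e-6, 100)])
        res = independent_filter(self.make_result(base, p), alpha=0.01)
        rej = int((res.table["padj"] < 0.01).sum())
        rej0 = int((bh_adjust(p) < 0.01).sum())
        assert rej >= rej0
        assert res.table["independent_filtered"].sum() > 0

    def test_all_null_high_count_robust(self):
        rng = np.random.default_rng(3)
        res = independent_filter(
            self.make_result(rng.uniform(100, 200, 300), rng.uniform(size=300))
        )
        assert int((res.table["padj"] < 0.01).sum()) == 0

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        base, p = rng.uniform(0, 100, 200), rng.uniform(size=200)
        a = independent_filter(self.make_result(base, p))
        b = independent_filter(self.make_result(base, p))
        assert a.table.equals(b.table) and a.filter_threshold == b.filter_threshold


class TestCallSignificant:
    @pytest.mark.parametrize(
        "padj,lfc,threshold,expected",
        [
            (0.005, 1.2, 1.0, "up"),
            (0.005, 0.8, 1.0, ""),
            (0.005, 0.8, 0.5, "up"),
            (0.011, 1.5, 1.0, ""),
            (0.005, -0.6, 0.5, "down"),
        ],
    )
    def test_threshold_boundaries(self, padj, lfc, threshold, expected):
        df = pd.DataFrame(
            {
                "baseMean": [10.0],
                "log2FoldChange": [lfc],
                "lfcSE": [1.0],
                "stat": [0.0],
                "pvalue": [padj],
                "padj": [padj],
                "cooks_outlier": False,
                "independent_filtered": False,
                "significant": False,
                "direction": "",
            },
            index=["f"],
        )
        res = call_significant(DEResult(df), alpha=0.01, lfc_threshold=threshold)
        row = res.table.iloc[0]
        assert row["significant"] == bool(expected)
        assert row["direction"] == expected


class TestPooledPirna:
    def test_empty_gene_table_equals_standalone(self):
        pir, _ = simulate_count_table(80, 0.0, 0.05, 2, seed=71, feature_prefix="p")
        empty = CountTable(pd.DataFrame(index=[], columns=pir.counts.columns), pir.samples)
        pooled = pooled_pirna_test(empty, pir, CONTRAST)
        alone = run_de_pipeline(pir, CONTRAST, alpha=0.01, lfc_threshold=0.5)
        assert np.allclose(
            pooled.table["log2FoldChange"], alone.table["log2FoldChange"], equal_nan=True
        )

    def test_global_shift_anchored_by_genes(self):
        """A global piRNA down-shift is recovered because size factors are
        dominated by the stable gene background."""
        genes, _ = simulate_count_table(
            2000, 0.0, 0.05, 2, seed=81, feature_prefix="g"
        )
        pir, _ = simulate_count_table(
            100, -2.0, 0.05, 2, mean_log=np.log(800), seed=82, feature_prefix="p"
        )
        res = pooled_pirna_test(genes, pir, CONTRAST)
        med = res.table["log2FoldChange"].median()
        assert med == pytest.approx(-2.0, abs=0.3)

    def test_sample_mismatch_rejected(self):
        genes, _ = simulate_count_table(10, 0.0, 0.05, 2, seed=91)
        pir, _ = simulate_count_table(10, 0.0, 0.05, 3, seed=92)
        with pytest.raises(ValueError, match="same samples"):
            pooled_pirna_test(genes, pir, CONTRAST)
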