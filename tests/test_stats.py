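"""Statistics layer against independent textbook computations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import cnatrack as ct


def bh_stepup_reference(p):
    """Independent hand implementation of the BH step-up q-values."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = running
    return q


class TestBenjaminiHochberg:
    def test_worked_stepup(self):
        q = ct.benjamini_hochberg([0.005, 0.01, 0.03, 0.04])
        assert np.allclose(q, [0.02, 0.02, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert ct.benjamini_hochberg([0.2]) == pytest.approx([0.2])

    def test_all_equal_stay_equal(self):
        q = ct.benjamini_hochberg([0.03] * 5)
        assert np.allclose(q, 0.03)

    def test_rejects_out_of_range(self):
        for bad in ([0.0, 0.5], [0.5, 1.5], [np.nan]):
            with pytest.raises(ValueError):
                ct.benjamini_hochberg(bad)

    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_matches_reference_and_invariants(self, p):
        q = ct.benjamini_hochberg(p)
        assert np.allclose(q, bh_stepup_reference(p), atol=1e-12)
        assert np.all(q >= np.asarray(p) - 1e-12)
        assert np.all(q <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert ct.pearson_correlation(x, x)[0] == pytest.approx(1.0)
        assert ct.pearson_correlation(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=30), rng.normal(size=30)
        r, p = ct.pearson_correlation(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        r_ref = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert r == pytest.approx(r_ref, abs=1e-12)
        t = r_ref * np.sqrt(28 / (1 - r_ref ** 2))
        assert p == pytest.approx(2 * sps.t.sf(abs(t), df=28), abs=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            ct.pearson_correlation([1, 1, 1], [1, 2, 3])


def pooled_t_reference(a, b):
    """Textbook pooled-variance two-sample t."""
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    t = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * sps.t.sf(abs(t), df=na + nb - 2)
    return t, p


class TestDifferentialLogR:
    def _matrix(self, rng, n_genes=10, n_per_group=6):
        cols = [f"g{i}" for i in range(n_per_group)] + \
               [f"n{i}" for i in range(n_per_group)]
        labels = pd.Series(["GR"] * n_per_group + ["NR"] * n_per_group, index=cols)
        data = rng.normal(size=(n_genes, 2 * n_per_group))
        return pd.DataFrame(data, index=[f"gene{i}" for i in range(n_genes)],
                            columns=cols), labels

    def test_identical_groups_t_zero_p_one(self):
        cols = ["a", "b", "c", "d"]
        df = pd.DataFrame([[1.0, 2.0, 1.0, 2.0]], index=["g"], columns=cols)
        labels = pd.Series(["GR", "GR", "NR", "NR"], index=cols)
        res = ct.differential_logr(df, labels)
        assert res.loc["g", "t_stat"] == pytest.approx(0.0)
        assert res.loc["g", "p"] == pytest.approx(1.0)

    def test_label_swap_negates_t_keeps_p(self):
        rng = np.random.default_rng(0)
        df, labels = self._matrix(rng)
        res = ct.differential_logr(df, labels)
        swapped = labels.map({"GR": "NR", "NR": "GR"})
        res2 = ct.differential_logr(df, swapped)
        assert np.allclose(res2["t_stat"], -res["t_stat"], atol=1e-12)
        assert np.allclose(res2["p"], res["p"], atol=1e-12)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(1)
        df, labels = self._matrix(rng)
        res = ct.differential_logr(df, labels)
        for gene in df.index:
            a = df.loc[gene, labels == "GR"].to_numpy()
            b = df.loc[gene, labels == "NR"].to_numpy()
            t_ref, p_ref = pooled_t_reference(a, b)
            assert res.loc[gene, "t_stat"] == pytest.approx(t_ref, abs=1e-10)
            assert res.loc[gene, "p"] == pytest.approx(p_ref, abs=1e-10)

    def test_null_p_values_uniform(self):
        # no group effect: p across 1000 genes should be uniform
        rng = np.random.default_rng(2)
        df, labels = self._matrix(rng, n_genes=1000, n_per_group=8)
        res = ct.differential_logr(df, labels)
        assert sps.kstest(res["p"], "uniform").pvalue > 0.01

    def test_small_group_gene_skipped(self):
        cols = ["a", "b", "c", "d"]
        df = pd.DataFrame([[1.0, 2.0, 1.5, 2.5], [1.0, np.nan, np.nan, 2.0]],
                          index=["ok", "thin"], columns=cols)
        labels = pd.Series(["GR", "GR", "NR", "NR"], index=cols)
        res = ct.differential_logr(df, labels)
        assert "thin" not in res.index and "ok" in res.index


class TestCompareGiiGroups:
    def test_three_identical_groups(self):
        vals = [1, 2, 3] * 3
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = ct.compare_gii_groups(vals, labels)
        assert res.kind == "anova"
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_two_groups_equal_means(self):
        res = ct.compare_gii_groups([1, 3, 2, 2], ["a", "a", "b", "b"])
        assert res.kind == "t"
        assert res.statistic == pytest.approx(0.0)

    def test_anova_matches_sum_of_squares(self):
        rng = np.random.default_rng(7)
        groups = [rng.normal(loc=m, size=5) for m in (0.0, 0.5, 1.0)]
        vals = np.concatenate(groups)
        labels = np.repeat(["a", "b", "c"], 5)
        res = ct.compare_gii_groups(vals, labels)
        grand = vals.mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_ref = (ss_between / 2) / (ss_within / 12)
        assert res.statistic == pytest.approx(f_ref, abs=1e-10)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            ct.compare_gii_groups([1, 2, 3], ["a", "a", "b"])


class TestExpressionFilter:
    def test_exact_linear_coupling_kept(self):
        logr = pd.DataFrame([[0.0, 0.2, 0.4, 0.6]], index=["g"],
                            columns=list("abcd"))
        expr = 2 * logr + 1
        res = ct.expression_correlation_filter(logr, expr)
        assert res.loc["g", "kept"]
        assert res.loc["g", "r"] == pytest.approx(1.0)

    def test_constant_expression_dropped(self):
        logr = pd.DataFrame([[0.0, 0.2, 0.4, 0.6]], index=["g"],
                            columns=list("abcd"))
        expr = pd.DataFrame([[1.0, 1.0, 1.0, 1.0]], index=["g"],
                            columns=list("abcd"))
        res = ct.expression_correlation_filter(logr, expr)
        assert not res.loc["g", "kept"]
        assert np.isnan(res.loc["g", "r"])

    def test_too_few_pairs_dropped_with_warning(self, caplog):
        logr = pd.DataFrame([[0.1, np.nan, np.nan, 0.2]], index=["g"],
                            columns=list("abcd"))
        expr = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["g"],
                            columns=list("abcd"))
        with caplog.at_level("WARNING"):
            res = ct.expression_correlation_filter(logr, expr)
        assert not res.loc["g", "kept"]

    def test_ground_truth_agreement(self, default_cohort):
        cfg, cohort, truth = default_cohort
        wk0 = [p for p in cohort.profiles()
               if p.timepoint_weeks == 0 and p.quality == "good"]
        logr = ct.gene_logr_matrix(wk0, cohort.annotation)
        res = ct.expression_correlation_filter(logr, cohort.expression)
        joined = res.join(truth.genes.set_index("gene"))
        agree = (joined["kept"] == (joined["true_r"] >= 0.5)).mean()
        assert agree > 0.9


class TestRegionMerging:
    def test_adjacent_significant_genes_merge(self, default_bins):
        ann = pd.DataFrame({
            "gene": ["a", "b", "c"],
            "chrom": ["1", "1", "5"],
            "start": [100_000, 1_100_000, 100_000],
            "end": [120_000, 1_120_000, 120_000]})
        results = pd.DataFrame(
            {"significant": [True, True, True]}, index=["a", "b", "c"])
        regions = ct.merge_significant_regions(results, ann, default_bins)
        assert len(regions) == 2
        assert set(regions["n_genes"]) == {2, 1}
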