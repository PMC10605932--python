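import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from gmnet.stats import (
    ancova_group_test,
    chi_square_independence,
    correlation,
    correlation_table,
    fdr_adjust,
    one_way_anova_lsd,
    run_metric_comparisons,
)


def make_groups(rng, means, n=30, sd=1.0):
    values = np.concatenate([rng.normal(m, sd, n) for m in means])
    groups = np.concatenate([[f"g{i}"] * n for i in range(len(means))])
    return values, groups


class TestOneWayAnovaLSD:
    def test_matches_scipy_omnibus(self, rng):
        values, groups = make_groups(rng, [0.0, 0.3, 1.0])
        res = one_way_anova_lsd(values, groups)
        ref = sps.f_oneway(*[values[groups == g] for g in ("g0", "g1", "g2")])
        assert res.F == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_two_group_lsd_equals_pooled_t_test(self, rng):
        values, groups = make_groups(rng, [0.0, 0.6], n=25)
        res = one_way_anova_lsd(values, groups)
        ref = sps.ttest_ind(values[groups == "g0"], values[groups == "g1"])
        assert res.pairwise[("g0", "g1")] == pytest.approx(ref.pvalue)

    def test_all_constant_flagged_degenerate(self):
        res = one_way_anova_lsd(np.ones(20), ["a"] * 10 + ["b"] * 10)
        assert "degenerate-constant" in res.flags
        assert np.isnan(res.F)

    def test_zero_within_variance_with_shift_gives_p_zero(self):
        values = np.array([1.0] * 5 + [2.0] * 5)
        res = one_way_anova_lsd(values, ["a"] * 5 + ["b"] * 5)
        assert "zero-within-variance" in res.flags
        assert res.p == 0.0

    def test_null_p_values_approximately_uniform(self):
        ps = []
        for seed in range(300):
            r = np.random.default_rng(seed)
            values, groups = make_groups(r, [0.0, 0.0, 0.0], n=12)
            ps.append(one_way_anova_lsd(values, groups).p)
        ps = np.array(ps)
        assert abs((ps < 0.05).mean() - 0.05) < 0.035
        ks = sps.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_power_for_unit_shift(self):
        hits = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            values, groups = make_groups(r, [0.0, 0.0, 1.0], n=50)
            hits += one_way_anova_lsd(values, groups).p < 0.001
        assert hits >= 38

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            one_way_anova_lsd([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestAncova:
    def test_constant_covariates_collapse_to_anova(self, rng):
        values, groups = make_groups(rng, [0.0, 0.5, 1.0], n=20)
        cov = pd.DataFrame({"c1": np.zeros(60), "c2": np.full(60, 3.0)})
        res = ancova_group_test(values, groups, cov)
        ref = one_way_anova_lsd(values, groups)
        assert res.F == pytest.approx(ref.F, abs=1e-10)
        for pair, p in ref.pairwise.items():
            assert res.pairwise[pair] == pytest.approx(p, abs=1e-10)

    def test_confounded_null_keeps_nominal_size(self):
        rejections = 0
        n_rep = 300
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            age = r.normal(60, 8, 60)
            y = 2.0 * age + r.normal(0, 10, 60)
            groups = np.repeat(["a", "b", "c"], 20)
            res = ancova_group_test(y, groups, pd.DataFrame({"age": age}))
            rejections += res.p < 0.05
        # binomial 95% band around alpha = 0.05
        band = 1.96 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rejections / n_rep - 0.05) < band + 1e-9

    def test_recovers_pure_group_shift_in_adjusted_means(self):
        # SE of the mean difference is sqrt(2/n); n=200 makes +/-0.2 a ~95%
        # interval for recovering a unit shift
        hits = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            n = 200
            groups = np.repeat(["a", "b"], n)
            age = r.normal(60, 8, 2 * n)
            delta = 1.0
            y = r.normal(0, 1, 2 * n) + (groups == "b") * delta
            res = ancova_group_test(y, groups, pd.DataFrame({"age": age}))
            est = res.group_means["b"] - res.group_means["a"]
            hits += abs(est - delta) < 0.2
        assert hits >= 36

    def test_covariate_adjustment_removes_confound_bias(self, rng):
        # group b is older; age drives y; adjusted means should agree
        n = 200
        groups = np.repeat(["a", "b"], n)
        age = np.where(groups == "b", 70, 50) + rng.normal(0, 2, 2 * n)
        y = 0.1 * age + rng.normal(0, 0.2, 2 * n)
        res = ancova_group_test(y, groups, pd.DataFrame({"age": age}))
        raw_diff = y[groups == "b"].mean() - y[groups == "a"].mean()
        adj_diff = res.group_means["b"] - res.group_means["a"]
        assert abs(raw_diff) > 1.5
        assert abs(adj_diff) < 0.5

    def test_rank_deficiency_rejected(self, rng):
        values, groups = make_groups(rng, [0, 1], n=10)
        cov = pd.DataFrame({"x": np.arange(20.0), "y": 2 * np.arange(20.0)})
        with pytest.raises(ValueError, match="rank-deficient"):
            ancova_group_test(values, groups, cov)


class TestChiSquare:
    def test_alcohol_by_group_contingency_from_cohort_table(self):
        # yes/no counts per group: 24/25, 30/91, 20/54
        res = chi_square_independence([[24, 25], [30, 91], [20, 54]])
        assert res["df"] == 2
        assert res["p"] == pytest.approx(0.006, abs=5e-4)

    def test_identical_row_proportions_give_zero_statistic(self):
        res = chi_square_independence([[10, 20], [20, 40], [5, 10]])
        assert res["chi2"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_diagonal_2x2_hand_value(self):
        res = chi_square_independence([[10, 0], [0, 10]])
        assert res["chi2"] == pytest.approx(20.0)
        assert res["df"] == 1

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError, match="empty row or column"):
            chi_square_independence([[0, 0], [3, 4]])

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError, match="counts"):
            chi_square_independence([[1.5, 2], [3, 4]])


class TestCorrelation:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        res = correlation(x, 2 * x)
        assert res.r == pytest.approx(1.0)
        assert res.kind == "pearson"

    def test_independent_samples_near_zero(self):
        hits = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            res = correlation(r.standard_normal(1000), r.standard_normal(1000))
            hits += abs(res.r) < 0.1
        assert hits >= 38

    def test_partial_correlation_removes_shared_confounder(self, rng):
        n = 500
        z = rng.standard_normal(n)
        x = z + rng.standard_normal(n) * 0.5
        y = z + rng.standard_normal(n) * 0.5
        raw = correlation(x, y)
        partial = correlation(x, y, covariates=pd.DataFrame({"z": z}))
        assert raw.r > 0.5
        assert abs(partial.r) < 0.15
        assert partial.kind == "partial"

    def test_partial_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        n = 80
        df = pd.DataFrame({
            "x": rng.standard_normal(n),
            "y": rng.standard_normal(n),
            "c1": rng.standard_normal(n),
            "c2": rng.standard_normal(n),
        })
        df["y"] += 0.5 * df["x"] + 0.3 * df["c1"]
        res = correlation(df["x"].to_numpy(), df["y"].to_numpy(),
                          covariates=df[["c1", "c2"]])
        ref = pg.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            correlation(np.ones(10), np.arange(10.0))


class TestFDR:
    def test_hand_worked_bh_example(self):
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.037])[0] == pytest.approx(0.037)

    def test_q_dominates_p_elementwise(self, rng):
        p = rng.random(200)
        assert np.all(fdr_adjust(p) >= p)

    def test_matches_naive_sort_and_scan_oracle(self, rng):
        def naive_bh(p):
            p = np.asarray(p, dtype=float)
            m = p.size
            order = np.argsort(p, kind="stable")
            scaled = p[order] * m / (np.arange(m) + 1)
            adj = np.minimum.accumulate(scaled[::-1])[::-1].clip(max=1)
            out = np.empty(m)
            out[order] = adj
            return out

        for _ in range(300):
            p = rng.random(rng.integers(1, 40))
            assert np.allclose(fdr_adjust(p), naive_bh(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="p-values"):
            fdr_adjust([0.5, 1.2])


class TestReportTables:
    def _toy_tables(self, rng, n=12):
        groups = np.repeat(["a", "b", "c"], n)
        glob = pd.DataFrame({m: rng.standard_normal(3 * n)
                             for m in ("Eglob", "Eloc", "Lp", "Cp",
                                       "gamma", "lambda", "sigma")})
        from gmnet.regions import aal90_table

        nodal = pd.DataFrame(rng.standard_normal((3 * n, 90)),
                             columns=list(aal90_table()["abbreviation"]))
        cov = pd.DataFrame({
            "age": rng.normal(60, 8, 3 * n),
            "sex": rng.integers(0, 2, 3 * n).astype(float),
            "education": rng.normal(12, 3, 3 * n),
            "tiv": rng.normal(1.6, 0.15, 3 * n),
        })
        return glob, nodal, groups, cov

    def test_row_count_is_seven_global_plus_ninety_nodal(self, rng):
        glob, nodal, groups, cov = self._toy_tables(rng)
        table = run_metric_comparisons(glob, nodal, groups, cov)
        assert len(table) == 97
        assert (table["kind"] == "global").sum() == 7
        assert (table["kind"] == "nodal").sum() == 90

    def test_nodal_rows_carry_module_labels(self, rng):
        glob, nodal, groups, cov = self._toy_tables(rng)
        table = run_metric_comparisons(glob, nodal, groups, cov)
        acg = table.loc[table["outcome"] == "ACG.L"].iloc[0]
        assert acg["module"] == "DMN"

    def test_null_nodal_rejection_rate_near_alpha(self, rng):
        glob, nodal, groups, cov = self._toy_tables(rng, n=20)
        table = run_metric_comparisons(glob, nodal, groups, cov)
        nodal_rows = table[table["kind"] == "nodal"]
        # 90 independent null outcomes: significant fraction near 5%
        assert (nodal_rows["p"] < 0.05).mean() < 0.15

    def test_correlation_table_families_and_fdr(self, rng):
        glob, nodal, groups, cov = self._toy_tables(rng)
        scores = pd.DataFrame({s: rng.standard_normal(len(groups))
                               for s in ("MoCA", "AVLT", "SDMT", "SCWT",
                                         "TMT_BA")})
        table = correlation_table(glob[["Eglob", "Eloc", "Lp"]], scores,
                                  groups, covariates=cov)
        # 3 groups x 2 kinds x (3 metrics x 5 scores)
        assert len(table) == 3 * 2 * 15
        for (_, _), fam in table.groupby(["group", "kind"]):
            assert np.allclose(np.sort(fam["q"]),
                               np.sort(fdr_adjust(fam["p"].to_numpy())))
        assert np.all(table["q"] >= table["p"] - 1e-12)
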