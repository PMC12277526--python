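import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dtialps.stats import (
    omnibus_three_group,
    posthoc_pairwise,
    ancova_group_effect,
    logistic_or,
    partial_correlation,
    two_sample_compare,
    chi_square_counts,
    bh_adjust,
    run_full_stats,
    expected_report_keys,
)
from dtialps import generate_cohort_table
from dtialps.presets import make_preset


def _three_groups(rng, means=(0.0, 0.0, 0.0), n=40, sd=1.0):
    values = np.concatenate([rng.normal(m, sd, n) for m in means])
    groups = np.repeat(["A", "B", "C"], n)
    return values, groups


class TestOmnibus:
    def test_identical_pattern_gives_null_f(self):
        base = np.arange(1.0, 11.0)
        values = np.concatenate([base, base, base])
        groups = np.repeat(["A", "B", "C"], 10)
        res = omnibus_three_group(values, groups)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0, abs=1e-9)

    def test_anova_route_and_f_matches_sufficient_statistics(self):
        rng = np.random.default_rng(0)
        values, groups = _three_groups(rng, means=(0, 0, 1), n=40)
        res = omnibus_three_group(values, groups)
        assert res.route == "anova"
        # closed-form F from group sums (textbook decomposition)
        parts = [values[groups == g] for g in ("A", "B", "C")]
        grand = values.mean()
        ssb = sum(p.size * (p.mean() - grand) ** 2 for p in parts)
        ssw = sum(((p - p.mean()) ** 2).sum() for p in parts)
        f_oracle = (ssb / 2) / (ssw / (values.size - 3))
        assert res.statistic == pytest.approx(f_oracle, rel=1e-12)
        assert res.df == (2, 117)

    def test_skewed_data_routes_to_kruskal_wallis(self):
        taken = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            values = np.concatenate([rng.lognormal(0, 1.2, 30) for _ in range(3)])
            groups = np.repeat(["A", "B", "C"], 30)
            res = omnibus_three_group(values, groups)
            taken += res.route == "kruskal_wallis"
        assert taken >= 190  # ≥ 95% of replicates

    def test_all_constant_groups_rejected(self):
        values = np.repeat([1.0, 2.0, 3.0], 5)
        groups = np.repeat(["A", "B", "C"], 5)
        with pytest.raises(ValueError, match="zero within-group variance"):
            omnibus_three_group(values, groups)


class TestPosthoc:
    def test_bh_step_up_hand_oracle(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_identical_groups_give_p_near_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        values = np.concatenate([x, x])
        groups = np.repeat(["A", "B"], 30)
        res = posthoc_pairwise(values, groups, route="anova")
        assert res.pairwise[0]["p"] > 0.99

    def test_dunn_on_separated_groups_detects_difference(self):
        rng = np.random.default_rng(2)
        values = np.concatenate(
            [rng.lognormal(0, 0.3, 40), rng.lognormal(0, 0.3, 40), rng.lognormal(2, 0.3, 40)]
        )
        groups = np.repeat(["A", "B", "C"], 40)
        res = posthoc_pairwise(values, groups, route="kruskal_wallis")
        by_pair = {(r["a"], r["b"]): r for r in res.pairwise}
        assert by_pair[("A", "C")]["p_adjusted"] < 0.001
        assert by_pair[("A", "B")]["p_adjusted"] > 0.05

    @given(st.lists(st.floats(min_value=1e-8, max_value=1.0), min_size=1, max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_bh_matches_textbook_min_over_tail(self, pvals):
        """Adjusted p_i = min over j with p_(j) ≥ p_(i) of m·p_(j)/j, capped at 1."""
        p = np.asarray(pvals)
        m = p.size
        order = np.argsort(p)
        ranked = p[order]
        oracle_sorted = np.minimum.accumulate((m * ranked / np.arange(1, m + 1))[::-1])[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(oracle_sorted, 1.0)
        assert np.allclose(bh_adjust(p), oracle, atol=1e-12)

    def test_bh_preserves_raw_p_ordering(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=10)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestAncova:
    def test_outcome_equal_to_covariate_gives_null_group_effect(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=60)
        groups = np.repeat(["X", "Y"], 30)
        res = ancova_group_effect(z, groups, covariates=pd.DataFrame({"z": z}))
        assert abs(res.effect["coefficient"]) < 1e-10

    def test_recovers_known_group_coefficient(self):
        rng = np.random.default_rng(5)
        n = 76
        groups = np.repeat(["DMNC", "DMMCI"], n // 2)
        ind = (groups == "DMMCI").astype(float)
        z = rng.normal(size=n)
        y = 0.12 * ind + 0.5 * z + rng.normal(0, 0.01, n)
        res = ancova_group_effect(y, groups, covariates=pd.DataFrame({"z": z}))
        assert res.effect["coefficient"] == pytest.approx(0.12, abs=0.01)
        # independent normal-equations oracle
        X = np.column_stack([np.ones(n), ind, z])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.effect["coefficient"] == pytest.approx(beta[1], abs=1e-10)
        assert res.p < 1e-6

    def test_duplicated_covariate_rejected(self):
        rng = np.random.default_rng(6)
        z = rng.normal(size=40)
        groups = np.repeat(["X", "Y"], 20)
        with pytest.raises(ValueError, match="collinear"):
            ancova_group_effect(
                rng.normal(size=40), groups,
                covariates=pd.DataFrame({"z": z, "z2": z}),
            )

    def test_missing_covariates_dropped_and_counted(self):
        rng = np.random.default_rng(7)
        z = rng.normal(size=40)
        z[:4] = np.nan
        groups = np.repeat(["X", "Y"], 20)
        res = ancova_group_effect(rng.normal(size=40), groups, pd.DataFrame({"z": z}))
        assert res.n_dropped == 4
        assert res.n == 36


class TestLogistic:
    def test_two_by_two_matches_cross_product_ratio(self):
        # exposure/outcome counts a=20, b=10, c=10, d=20 → OR = ad/bc = 4
        outcome = np.concatenate([np.ones(30), np.zeros(30)])
        predictor = np.concatenate([np.ones(20), np.zeros(10), np.ones(10), np.zeros(20)])
        res = logistic_or(outcome, predictor)
        assert res.effect["or"] == pytest.approx(4.0, abs=1e-6)
        assert res.effect["ci_low"] < 4.0 < res.effect["ci_high"]

    def test_null_coverage_of_wald_interval(self):
        """Independent predictor → CI covers OR = 1 in ≥ 93% of replicates."""
        cover = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            outcome = rng.permutation(np.repeat([0.0, 1.0], 30))
            predictor = rng.normal(size=60)
            res = logistic_or(outcome, predictor)
            cover += res.effect["ci_low"] <= 1.0 <= res.effect["ci_high"]
        assert cover >= 186

    def test_percent_scaling_rescales_coefficient(self):
        rng = np.random.default_rng(8)
        x = rng.normal(1.6, 0.2, 120)
        y = (rng.uniform(size=120) < 1 / (1 + np.exp(-(x - 1.6) * 3))).astype(float)
        raw = logistic_or(y, x, scale_percent=False)
        pct = logistic_or(y, x, scale_percent=True)
        assert pct.effect["coefficient"] == pytest.approx(raw.effect["coefficient"] / 100, rel=1e-6)

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            logistic_or(np.ones(20), np.arange(20.0))

    def test_complete_separation_rejected(self):
        x = np.concatenate([np.arange(10.0), np.arange(20.0, 30.0)])
        y = np.concatenate([np.zeros(10), np.ones(10)])
        with pytest.raises(ValueError, match="separation"):
            logistic_or(y, x)


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self):
        from scipy.stats import pearsonr

        rng = np.random.default_rng(9)
        x, y = rng.normal(size=(2, 50))
        res = partial_correlation(x, y)
        r, p = pearsonr(x, y)
        assert res.effect["r"] == pytest.approx(r, abs=1e-12)
        assert res.p == pytest.approx(p, abs=1e-10)

    def test_confounded_pair_has_null_partial_r(self):
        # 10-row fixture: x and y both driven by z, independent otherwise
        z = np.array([0.1, 0.5, 0.9, 1.4, 1.8, 2.2, 2.7, 3.1, 3.6, 4.0])
        ex = np.array([0.3, -0.2, 0.1, -0.4, 0.2, 0.0, -0.1, 0.3, -0.3, 0.1])
        ey = np.array([-0.1, 0.2, -0.3, 0.1, 0.0, 0.3, -0.2, -0.1, 0.2, 0.0])
        x, y = 2 * z + ex, -1.5 * z + ey
        from scipy.stats import pearsonr

        assert abs(pearsonr(x, y)[0]) > 0.9  # strong marginal correlation
        res = partial_correlation(x, y, pd.DataFrame({"z": z}))
        # brute-force residualization oracle
        A = np.column_stack([np.ones(10), z])
        rx = x - A @ np.linalg.lstsq(A, x, rcond=None)[0]
        ry = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert res.effect["r"] == pytest.approx(oracle, abs=1e-12)
        assert abs(res.effect["r"]) < 0.5

    def test_perfect_dependence_gives_unit_r(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=30)
        cov = pd.DataFrame({"z": rng.normal(size=30)})
        res = partial_correlation(x, x.copy(), cov)
        assert res.effect["r"] == pytest.approx(1.0, abs=1e-12)

    def test_matches_pingouin_oracle(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        for _ in range(10):
            df = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("xyzw"))
            res = partial_correlation(df.x, df.y, df[["z", "w"]])
            ora = pingouin.partial_corr(df, x="x", y="y", covar=["z", "w"])
            p_col = "p_val" if "p_val" in ora.columns else "p-val"
            assert res.effect["r"] == pytest.approx(float(ora["r"].iloc[0]), abs=1e-10)
            assert res.p == pytest.approx(float(ora[p_col].iloc[0]), abs=1e-8)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            partial_correlation(np.ones(20), np.arange(20.0))


class TestTwoSample:
    def test_identical_groups_give_p_near_one(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=25)
        res = two_sample_compare(np.concatenate([x, x]), np.repeat(["a", "b"], 25))
        assert res.p > 0.99

    def test_t_statistic_matches_pooled_variance_formula(self):
        a = np.array([4.1, 5.2, 3.9, 4.8, 5.0, 4.5])
        b = np.array([5.6, 6.1, 5.9, 6.4, 5.8, 6.2])
        res = two_sample_compare(np.concatenate([a, b]), np.repeat(["a", "b"], 6))
        assert res.route == "t_test"
        sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / 10
        t_oracle = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 6 + 1 / 6))
        assert res.statistic == pytest.approx(t_oracle, rel=1e-12)
        assert res.df == 10

    def test_skewed_data_routes_to_mann_whitney(self):
        taken = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            values = np.concatenate([rng.lognormal(0, 1.5, 30) for _ in range(2)])
            res = two_sample_compare(values, np.repeat(["a", "b"], 30))
            taken += res.route == "mann_whitney"
        assert taken >= 95

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            two_sample_compare(np.arange(10.0), np.repeat(["a"], 10))


class TestChiSquare:
    def test_proportional_table_gives_zero(self):
        res = chi_square_counts([[10, 20, 30], [20, 40, 60]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_two_by_two_matches_closed_form(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 50, size=4)
            res = chi_square_counts([[a, b], [c, d]])
            n = a + b + c + d
            oracle = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            assert res.statistic == pytest.approx(oracle, rel=1e-12)
            assert res.df == 1

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_counts([[0, 0], [1, 2]])


class TestFullStats:
    @pytest.fixture(scope="class")
    def cohort(self):
        table = generate_cohort_table(
            [make_preset(g) for g in ("HC", "DMNC", "DMMCI")], (37, 37, 39), seed=42
        )
        return table

    def test_report_schema_is_fixed(self, cohort):
        report = run_full_stats(cohort)
        assert sorted(report.keys()) == sorted(expected_report_keys())

    def test_missing_columns_listed(self, cohort):
        with pytest.raises(ValueError, match="alps_mean"):
            run_full_stats(cohort.drop(columns=["alps_mean"]))

    def test_calibrated_cohort_shows_left_exceeding_right(self, cohort):
        for g in ("HC", "DMNC", "DMMCI"):
            sub = cohort[cohort.group == g]
            assert sub.alps_left.mean() > sub.alps_right.mean()

    def test_hippocampal_coupling_detected_in_t2dm_only(self, cohort):
        report = run_full_stats(cohort)
        r_dm = report["partialcorr_hippo/T2DM/alps_mean~hippo_rd_left"].effect["r"]
        r_hc = report["partialcorr_hippo/HC/alps_mean~hippo_rd_left"].effect["r"]
        assert r_dm < -0.2  # generator couples RD to ALPS under disease
        assert abs(r_hc) < abs(r_dm)

    def test_pure_null_posthoc_fdr_controlled(self):
        """With all three groups drawn from one preset, the fraction of
        BH-significant ALPS post hoc contrasts stays at or below α."""
        hc = make_preset("HC")
        sig = total = 0
        for seed in range(200):
            t = generate_cohort_table([hc, hc, hc], (15, 15, 15), seed=seed)
            t = t.copy()
            t.loc[t.index[15:30], "group"] = "DMNC"
            t.loc[t.index[30:], "group"] = "DMMCI"
            for a in ("alps_left", "alps_right", "alps_mean"):
                omni = omnibus_three_group(t[a], t.group)
                post = posthoc_pairwise(t[a], t.group, omni.route)
                for rec in post.pairwise:
                    sig += rec["p_adjusted"] < 0.05
                    total += 1
        assert sig / total <= 0.05

    def test_ancova_power_monotone_in_sample_size(self):
        """A fixed ALPS group difference of 0.10 must be detected more often
        as the per-group n grows over {20, 40, 80}."""
        power = []
        for n in (20, 40, 80):
            hits = 0
            for seed in range(200):
                rng = np.random.default_rng(1000 * n + seed)
                groups = np.repeat(["DMNC", "DMMCI"], n)
                ind = (groups == "DMMCI").astype(float)
                z = rng.normal(size=2 * n)
                y = 1.68 - 0.10 * ind + 0.05 * z + rng.normal(0, 0.21, 2 * n)
                res = ancova_group_effect(y, groups, pd.DataFrame({"z": z}))
                hits += res.p < 0.05
            power.append(hits / 200)
        assert power[0] < power[1] < power[2]
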