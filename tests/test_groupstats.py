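"""ANOVA/Tukey, categorical goodness-of-fit, Bonferroni, factor analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenosom.groupstats import (bonferroni, category_distribution_chi2,
                                 compare_categories, compare_measures,
                                 gender_gof_chi2, oneway_anova,
                                 questionnaire_factors, tukey_posthoc)

CLUSTER_SIZES = (146, 121, 132, 131)


class TestAnova:
    def test_identical_group_means_give_zero(self):
        vals = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        grp = np.array([0, 0, 0, 1, 1, 1])
        assert oneway_anova(vals, grp).F == pytest.approx(0.0)

    def test_hand_sums_of_squares_oracle(self):
        # {1,2,3} vs {4,5,6}: SSB = 13.5 (1 df), SSW = 4 (4 df) -> F = 13.5
        vals = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        grp = np.array([0, 0, 0, 1, 1, 1])
        res = oneway_anova(vals, grp)
        assert res.F == pytest.approx(13.5)
        assert (res.df_between, res.df_within) == (1, 4)
        sp = stats.f_oneway(vals[:3], vals[3:])
        assert res.F == pytest.approx(sp.statistic)
        assert res.p == pytest.approx(sp.pvalue)

    def test_within_group_permutation_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal(30)
        grp = np.repeat([0, 1, 2], 10)
        base = oneway_anova(vals, grp).F
        shuffled = vals.copy()
        for g in range(3):
            idx = np.flatnonzero(grp == g)
            shuffled[idx] = shuffled[rng.permutation(idx)]
        assert oneway_anova(shuffled, grp).F == pytest.approx(base)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(1)
        vals = rng.standard_normal(40)
        grp = np.repeat([0, 1, 2, 3], 10)
        assert oneway_anova(3.7 * vals - 11.0, grp).F == pytest.approx(
            oneway_anova(vals, grp).F)

    def test_degenerate_variance_reported_not_coerced(self):
        vals = np.array([1.0, 1.0, 1.0, 1.0])
        grp = np.array([0, 0, 1, 1])
        res = oneway_anova(vals, grp)
        assert np.isnan(res.F)


class TestTukey:
    def test_identical_groups_p_one(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        tbl = tukey_posthoc(np.concatenate([g, g]),
                            np.repeat([0, 1], 4))
        assert tbl["p_adj"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_adjusted_p_not_below_pairwise_t(self):
        rng = np.random.default_rng(2)
        vals = rng.standard_normal(30) + np.repeat([0, 0.5, 1.0], 10)
        grp = np.repeat([0, 1, 2], 10)
        tbl = tukey_posthoc(vals, grp)
        for _, row in tbl.iterrows():
            a = vals[grp == row.group_a]
            b = vals[grp == row.group_b]
            t_p = stats.ttest_ind(a, b).pvalue
            assert row.p_adj >= t_p - 1e-12

    def test_singleton_group_flagged_untestable(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0, 9.0])
        grp = np.array([0, 0, 1, 1, 2])
        tbl = tukey_posthoc(vals, grp)
        bad = tbl[(tbl.group_a == 2) | (tbl.group_b == 2)]
        assert bad["p_adj"].isna().all()
        good = tbl[(tbl.group_a == 0) & (tbl.group_b == 1)]
        assert good["p_adj"].notna().all()

    def test_matches_studentized_range_monte_carlo_oracle(self):
        rng = np.random.default_rng(3)
        n, g = 8, 3
        vals = rng.standard_normal(n * g) + np.repeat([0.0, 0.8, 1.3], n)
        grp = np.repeat(np.arange(g), n)
        tbl = tukey_posthoc(vals, grp)
        groups = [vals[grp == i] for i in range(g)]
        df = n * g - g
        s2 = np.mean([v.var(ddof=1) for v in groups])
        # Monte-Carlo null of the studentized range statistic
        draws = 100_000
        means = rng.standard_normal((draws, g)) / np.sqrt(n)
        s2_null = stats.chi2.rvs(df, size=draws, random_state=rng) / df
        q_null = (means.max(axis=1) - means.min(axis=1)) / np.sqrt(s2_null / n)
        for _, row in tbl.iterrows():
            a, b = int(row.group_a), int(row.group_b)
            q_obs = abs(groups[a].mean() - groups[b].mean()) / np.sqrt(s2 / n)
            p_mc = np.mean(q_null >= q_obs)
            assert row.p_adj == pytest.approx(p_mc, abs=0.01)


class TestCategoricalChi2:
    @pytest.mark.parametrize("counts,expected", [
        ((43, 16, 15, 24), 14.931),   # under speech & language therapy
        ((36, 48, 52, 39), 6.755),    # referred for attention
    ])
    def test_published_worked_examples(self, counts, expected):
        res = category_distribution_chi2(counts, CLUSTER_SIZES)
        assert res.chi2 == pytest.approx(expected, abs=0.01)
        assert res.df == 3

    def test_proportional_counts_give_zero(self):
        sizes = (100, 200, 300, 400)
        counts = (10, 20, 30, 40)
        assert category_distribution_chi2(counts, sizes).chi2 == pytest.approx(0)

    def test_counts_exceeding_sizes_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            category_distribution_chi2((200, 0, 0, 0), CLUSTER_SIZES)

    @pytest.mark.parametrize("cluster,expected", [
        ((87, 59), 6.12),    # broad-deficits cluster: excess of girls
        ((105, 27), 6.80),   # age-appropriate cluster: excess of boys
    ])
    def test_gender_goodness_of_fit_examples(self, cluster, expected):
        chi2, _ = gender_gof_chi2(cluster, (366, 164))
        assert chi2 == pytest.approx(expected, abs=0.01)

    def test_gender_split_at_overall_proportion_gives_zero(self):
        chi2, p = gender_gof_chi2((183, 82), (366, 164))
        assert chi2 == pytest.approx(0.0)


class TestBonferroni:
    def test_definition_cap_and_family_of_one(self):
        assert bonferroni([0.01], m=7)[0] == pytest.approx(0.07)
        assert bonferroni([0.4], m=3)[0] == 1.0
        assert bonferroni([0.2], m=1)[0] == pytest.approx(0.2)

    def test_never_decreases(self):
        rng = np.random.default_rng(4)
        p = rng.random(20)
        assert np.all(bonferroni(p) >= p)
        assert np.all(bonferroni(p) <= 1.0)


class TestQuestionnaireFactors:
    def make_two_factor_data(self, n=400, noise=0.0, seed=5):
        rng = np.random.default_rng(seed)
        L = np.zeros((6, 2))
        L[:3, 0] = [0.9, 0.8, 0.85]
        L[3:, 1] = [0.9, 0.85, 0.8]
        F = rng.standard_normal((n, 2))
        X = F @ L.T + noise * rng.standard_normal((n, 6))
        cols = [f"s{i}" for i in range(6)]
        return pd.DataFrame(X, columns=cols), L

    def test_exact_two_factor_structure_recovered(self):
        df, L = self.make_two_factor_data(noise=0.0)
        sol = questionnaire_factors(df, n_factors=2)
        got = sol.loadings.to_numpy()
        # congruence up to sign/order
        best = 0.0
        for perm in ([0, 1], [1, 0]):
            for s0 in (1, -1):
                for s1 in (1, -1):
                    cand = np.column_stack([s0 * got[:, perm[0]],
                                            s1 * got[:, perm[1]]])
                    cong = np.mean([
                        np.dot(cand[:, j], L[:, j])
                        / (np.linalg.norm(cand[:, j]) * np.linalg.norm(L[:, j]))
                        for j in range(2)])
                    best = max(best, cong)
        assert best > 0.99

    def test_variance_identity_and_score_standardization(self):
        df, _ = self.make_two_factor_data(noise=0.4, seed=6)
        sol = questionnaire_factors(df, n_factors=2)
        assert sol.variance_per_component.sum() == pytest.approx(100.0)
        assert np.allclose(sol.scores.mean(), 0.0, atol=1e-10)
        assert np.allclose(sol.scores.std(ddof=1), 1.0)
        assert 0 < sol.variance_explained < 100

    def test_constant_subscale_rejected_by_name(self):
        df, _ = self.make_two_factor_data(noise=0.3, seed=7)
        df["flat"] = 2.0
        with pytest.raises(ValueError, match="flat"):
            questionnaire_factors(df, n_factors=2)


class TestFamilies:
    def test_compare_measures_bonferroni_within_family(self, default_cohort):
        cohort, labels = default_cohort
        modal = labels["generating_cluster"].to_numpy() - 1
        omni, pairwise = compare_measures(cohort.scores, modal,
                                          cohort.families)
        cog = omni[omni.family == "cognitive"]
        lea = omni[omni.family == "learning"]
        assert len(cog) == 7 and len(lea) == 3
        assert np.allclose(cog["p_corrected"],
                           np.minimum(1, cog["p_raw"] * 7))
        assert np.allclose(lea["p_corrected"],
                           np.minimum(1, lea["p_raw"] * 3))
        # generating clusters genuinely differ -> every omnibus significant
        assert (omni["p_corrected"] < 0.001).all()
        pairs_per_measure = pairwise.groupby("measure").size()
        assert (pairs_per_measure == 6).all()

    def test_compare_categories_counts_sum(self, default_cohort):
        cohort, labels = default_cohort
        modal = labels["generating_cluster"].to_numpy() - 1
        tbl = compare_categories(labels, modal, ["slt", "add_adhd"])
        count_cols = [c for c in tbl.columns if c.startswith("cluster_")]
        assert (tbl[count_cols].sum(axis=1).to_numpy()
                == labels[["slt", "add_adhd"]].sum().to_numpy()).all()
        assert (tbl["p_corrected"] >= tbl["p_raw"] - 1e-12).all()
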