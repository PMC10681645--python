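"""Group statistics: OLS residualization, ANOVA/t against sums-of-squares
oracles, Bonferroni arithmetic, bootstrap and clinical correlations."""

import numpy as np
import pandas as pd
import pytest

from morphoconn.group_stats import (anova_by_region, bonferroni_mask,
                                    bootstrap_agematched, clinical_correlation,
                                    pairwise_t, residualize)


def make_cov(n, seed=0, groups=("NC", "MCI", "AD")):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "group": np.resize(groups, n),
        "age": rng.uniform(60, 85, n),
        "sex": rng.integers(0, 2, n),
    })


class TestResidualize:
    def test_perfect_linear_fit_leaves_zero_residual(self):
        cov = make_cov(30, seed=1)
        rmcs = pd.DataFrame({1: 0.3 * cov["age"].to_numpy() - 2.0,
                             2: -0.1 * cov["age"].to_numpy() + 5.0})
        rmcs.index = cov["subject_id"]
        resid = residualize(rmcs, cov)
        assert np.linalg.norm(resid.to_numpy()) < 1e-10

    def test_residuals_orthogonal_to_design(self):
        cov = make_cov(50, seed=2)
        rng = np.random.default_rng(3)
        rmcs = pd.DataFrame(rng.normal(size=(50, 4)), index=cov["subject_id"])
        resid = residualize(rmcs, cov).to_numpy()
        for col in ("age", "sex"):
            assert np.abs(resid.T @ cov[col].to_numpy()).max() < 1e-8
        assert np.abs(resid.sum(axis=0)).max() < 1e-8

    def test_rank_deficient_design_rejected(self):
        cov = make_cov(10, seed=4)
        cov["age"] = 70.0
        cov["sex"] = 1
        rmcs = pd.DataFrame(np.zeros((10, 2)), index=cov["subject_id"])
        with pytest.raises(ValueError, match="rank-deficient"):
            residualize(rmcs, cov)


class TestAnova:
    def test_identical_groups_give_zero_F(self):
        block = np.random.default_rng(5).normal(size=(4, 3))
        rmcs = pd.DataFrame(np.vstack([block] * 3))
        groups = pd.Series(["NC"] * 4 + ["MCI"] * 4 + ["AD"] * 4)
        out = anova_by_region(rmcs, groups)
        assert np.allclose(out["F"], 0.0, atol=1e-20)

    def test_two_groups_F_equals_t_squared(self):
        rng = np.random.default_rng(6)
        rmcs = pd.DataFrame(rng.normal(size=(20, 5)))
        groups = pd.Series(["A"] * 10 + ["B"] * 10)
        f = anova_by_region(rmcs, groups, labels=("A", "B"))
        t = pairwise_t(rmcs, groups, ("A", "B"))
        assert np.allclose(f["F"], t["t"] ** 2, atol=1e-10)
        assert np.allclose(f["p"], t["p"], atol=1e-12)

    def test_matches_sums_of_squares_oracle(self):
        # 3 groups x 3 subjects, one region, hand decomposition
        vals = np.array([1.0, 2.0, 3.0, 2.0, 4.0, 6.0, 5.0, 5.0, 8.0])
        groups = pd.Series(["NC"] * 3 + ["MCI"] * 3 + ["AD"] * 3)
        rmcs = pd.DataFrame({1: vals})
        grand = vals.mean()
        means = [vals[:3].mean(), vals[3:6].mean(), vals[6:].mean()]
        ss_between = 3 * sum((m - grand) ** 2 for m in means)
        ss_within = sum(((vals[3 * k:3 * k + 3] - means[k]) ** 2).sum()
                        for k in range(3))
        expected_F = (ss_between / 2) / (ss_within / 6)
        out = anova_by_region(rmcs, groups)
        assert out["F"].iloc[0] == pytest.approx(expected_F, abs=1e-10)

    def test_empty_group_rejected(self):
        rmcs = pd.DataFrame(np.zeros((4, 2)))
        groups = pd.Series(["NC", "NC", "MCI", "MCI"])
        with pytest.raises(ValueError, match="empty"):
            anova_by_region(rmcs, groups)


class TestPairwiseT:
    def test_equal_samples_give_zero_t(self):
        block = np.random.default_rng(7).normal(size=(5, 3))
        rmcs = pd.DataFrame(np.vstack([block, block]))
        groups = pd.Series(["AD"] * 5 + ["NC"] * 5)
        out = pairwise_t(rmcs, groups, ("AD", "NC"))
        assert np.allclose(out["t"], 0.0, atol=1e-12)
        assert np.allclose(out["p"], 1.0)

    def test_antisymmetry_under_group_swap(self):
        rng = np.random.default_rng(8)
        rmcs = pd.DataFrame(rng.normal(size=(30, 4)))
        groups = pd.Series(["AD"] * 15 + ["NC"] * 15)
        fwd = pairwise_t(rmcs, groups, ("AD", "NC"))
        rev = pairwise_t(rmcs, groups, ("NC", "AD"))
        assert np.allclose(fwd["t"], -rev["t"], atol=1e-12)
        assert np.allclose(fwd["p"], rev["p"], atol=1e-12)

    def test_degenerate_constant_groups(self):
        rmcs = pd.DataFrame({1: [2.0, 2.0, 2.0, 2.0]})
        groups = pd.Series(["AD", "AD", "NC", "NC"])
        out = pairwise_t(rmcs, groups, ("AD", "NC"))
        assert out["t"].iloc[0] == 0.0
        assert out["p"].iloc[0] == 1.0

    def test_welch_variant_differs_under_unequal_variance(self):
        rng = np.random.default_rng(9)
        rmcs = pd.DataFrame({1: np.r_[rng.normal(0, 0.1, 10),
                                      rng.normal(0, 5.0, 40)]})
        groups = pd.Series(["AD"] * 10 + ["NC"] * 40)
        student = pairwise_t(rmcs, groups, ("AD", "NC"), equal_var=True)
        welch = pairwise_t(rmcs, groups, ("AD", "NC"), equal_var=False)
        assert student["t"].iloc[0] != pytest.approx(welch["t"].iloc[0])


class TestBonferroni:
    def test_threshold_arithmetic(self):
        assert bonferroni_mask(np.array([2.0e-4]), alpha=0.05, n=246)[0]
        assert not bonferroni_mask(np.array([0.05 / 246]), alpha=0.05, n=246)[0]

    def test_n_one_reduces_to_uncorrected(self):
        p = np.array([0.04, 0.06])
        assert bonferroni_mask(p, alpha=0.05, n=1).tolist() == [True, False]

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_mask(np.array([1.5]))


class TestBootstrap:
    def test_full_fraction_gives_perfect_correlation(self, planted_rmcs):
        rmcs, cov, _ = planted_rmcs
        rep = bootstrap_agematched(rmcs, cov, n_iter=5, frac=1.0, seed=0)
        assert np.allclose(rep.correlations, 1.0)
        assert rep.fraction_above == 1.0

    def test_deterministic_given_seed(self, planted_rmcs):
        rmcs, cov, _ = planted_rmcs
        a = bootstrap_agematched(rmcs, cov, n_iter=20, frac=0.8, seed=3)
        b = bootstrap_agematched(rmcs, cov, n_iter=20, frac=0.8, seed=3)
        assert np.array_equal(a.correlations, b.correlations)
        assert a.fraction_above == b.fraction_above

    def test_age_matching_is_enforced(self, planted_rmcs):
        from scipy.stats import f_oneway

        rmcs, cov, _ = planted_rmcs
        rep = bootstrap_agematched(rmcs, cov, n_iter=10, frac=0.8, seed=4)
        assert rep.n_failed == 0
        assert (rep.age_match_attempts >= 1).all()

    def test_invalid_fraction_rejected(self, planted_rmcs):
        rmcs, cov, _ = planted_rmcs
        with pytest.raises(ValueError):
            bootstrap_agematched(rmcs, cov, n_iter=2, frac=0.0, seed=0)


class TestClinical:
    def test_perfect_copy_gives_unit_correlation(self, planted_rmcs):
        rmcs, cov, _ = planted_rmcs
        adj_cov = cov.copy()
        region = rmcs.columns[0]
        adj_cov["MMSE"] = rmcs[region].to_numpy()
        out = clinical_correlation(rmcs, adj_cov, regions=[region], group="AD",
                                   measures=("MMSE",))
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_constant_score_flagged_undefined(self, planted_rmcs):
        rmcs, cov, _ = planted_rmcs
        c = cov.copy()
        c["MMSE"] = 25.0
        out = clinical_correlation(rmcs, c, regions=[rmcs.columns[0]],
                                   group="AD", measures=("MMSE",))
        assert out["undefined"].iloc[0]
        assert np.isnan(out["r"].iloc[0])

    def test_missing_values_dropped_pairwise(self, planted_rmcs):
        rmcs, cov, _ = planted_rmcs
        c = cov.copy()
        miss = c.index[(c["group"] == "AD")][:3]
        c.loc[miss, "ADAS-cog11"] = np.nan
        out = clinical_correlation(rmcs, c, regions=[rmcs.columns[0]],
                                   group="AD", measures=("ADAS-cog11",))
        assert np.isfinite(out["r"].iloc[0])

    def test_unknown_group_rejected(self, planted_rmcs):
        rmcs, cov, _ = planted_rmcs
        with pytest.raises(ValueError):
            clinical_correlation(rmcs, cov, group="XX")

    def test_clinical_tracks_rmcs_in_planted_regions(self, planted_rmcs):
        """Planted-region RMCS correlates positively with MMSE within MCI+AD:
        lower connectivity strength, worse cognition."""
        rmcs, cov, planted = planted_rmcs
        out = clinical_correlation(rmcs, cov, regions=sorted(planted),
                                   group="AD", measures=("MMSE",))
        assert out["r"].mean() > 0
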