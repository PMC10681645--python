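"""Map-expression association: region alignment, the univariate-PLS closed
form (cross-checked against scikit-learn), gene ranking, variogram
surrogates and surrogate p-values."""

import numpy as np
import pandas as pd
import pytest

from conftest import grf_map
from morphoconn.resources import AD_RISK_GENES
from morphoconn.synthetic_cohort import generate_atlas
from morphoconn.transcriptomics import (ExpressionMatrix,
                                        adrisk_gene_correlations,
                                        align_regions, empirical_variogram,
                                        ensemble_correlations, pls_fit,
                                        rank_genes, replicate_association,
                                        surrogate_pvalue,
                                        variogram_surrogates)


def random_problem(seed, n=40, G=30, signal=0.5):
    rng = np.random.default_rng(seed)
    x = pd.Series(rng.normal(size=n), index=pd.RangeIndex(1, n + 1))
    Y = pd.DataFrame(rng.normal(size=(n, G))
                     + signal * np.outer(x, rng.normal(size=G)),
                     index=x.index, columns=[f"g{j:03d}" for j in range(G)])
    return x, Y


class TestAlign:
    def test_missing_regions_removed_from_both(self):
        atlas = generate_atlas(246, seed=0)
        rng = np.random.default_rng(1)
        tmap = pd.Series(rng.normal(size=246), index=atlas.region_ids)
        df = pd.DataFrame(rng.normal(size=(246, 5)), index=atlas.region_ids)
        missing = list(range(1, 11))
        expr = ExpressionMatrix(df.drop(index=missing), tuple(missing))
        t2, e2 = align_regions(tmap, expr)
        assert len(t2) == 236 and len(e2) == 236
        assert list(t2.index) == list(e2.index)

    def test_empty_ledger_is_identity(self):
        x, Y = random_problem(2)
        t2, e2 = align_regions(x, ExpressionMatrix(Y))
        pd.testing.assert_series_equal(t2, x)

    def test_disjoint_regions_rejected(self):
        x, Y = random_problem(3)
        Y.index = pd.RangeIndex(1000, 1000 + len(Y))
        with pytest.raises(ValueError):
            align_regions(x, ExpressionMatrix(Y))


class TestPLS:
    @pytest.mark.parametrize("seed", range(5))
    def test_weights_proportional_to_covariances(self, seed):
        x, Y = random_problem(seed)
        res = pls_fit(x, Y)
        xz = (x - x.mean()) / x.std(ddof=1)
        Yz = (Y - Y.mean()) / Y.std(ddof=1)
        cov = Yz.T @ xz / (len(x) - 1)
        expected = cov / np.linalg.norm(cov)
        assert np.abs(res.weights.to_numpy() - expected.to_numpy()).max() < 1e-8

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_sklearn_first_component(self, seed):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        x, Y = random_problem(seed + 10)
        res = pls_fit(x, Y)
        Yz = (Y - Y.mean()) / Y.std(ddof=1)
        m = sklearn.PLSRegression(n_components=1, scale=True)
        m.fit(x.to_numpy().reshape(-1, 1), Yz)
        w_sk = m.y_weights_[:, 0]
        w_sk /= np.linalg.norm(w_sk)
        cos = abs(float(w_sk @ res.weights.to_numpy()))
        assert cos == pytest.approx(1.0, abs=1e-8)

    def test_rank_one_response_fully_explained(self):
        rng = np.random.default_rng(4)
        x = pd.Series(rng.normal(size=30))
        b = rng.normal(size=12)
        Y = pd.DataFrame(np.outer(x, b), index=x.index)
        res = pls_fit(x, Y)
        assert res.explained_variance == pytest.approx(1.0, abs=1e-12)
        assert abs(res.r) == pytest.approx(1.0, abs=1e-12)

    def test_constant_map_rejected(self):
        _, Y = random_problem(5)
        with pytest.raises(ValueError, match="constant"):
            pls_fit(pd.Series(np.ones(len(Y)), index=Y.index), Y)

    def test_noise_genes_dilute_explained_variance(self):
        x, Y = random_problem(6, G=20, signal=1.0)
        base = pls_fit(x, Y).explained_variance
        rng = np.random.default_rng(7)
        noisy = pd.concat([Y, pd.DataFrame(
            rng.normal(size=(len(Y), 20)), index=Y.index,
            columns=[f"n{j}" for j in range(20)])], axis=1)
        assert pls_fit(x, noisy).explained_variance < base

    def test_sign_coherence_under_map_negation(self):
        x, Y = random_problem(8)
        a = pls_fit(x, Y)
        b = pls_fit(-x, Y)
        assert np.allclose(a.weights, -b.weights, atol=1e-12)
        assert np.allclose(a.scores, -b.scores, atol=1e-12)
        assert a.explained_variance == pytest.approx(b.explained_variance)
        # score and map flip together, so their correlation is unchanged
        assert a.r == pytest.approx(b.r)


class TestRankGenes:
    def test_full_ranking_and_top_k(self):
        x, Y = random_problem(9, G=25)
        res = pls_fit(x, Y)
        ranking = rank_genes(res, k=25)
        assert len(ranking) == 25
        assert (np.diff(ranking["abs_weight"].to_numpy()) <= 1e-15).all()

    def test_ties_break_alphabetically(self):
        res = pls_fit(*random_problem(10, G=6))
        w = pd.Series([0.5, -0.5, 0.3, 0.3, -0.9, 0.1],
                      index=["b", "a", "d", "c", "e", "f"])
        res.weights = w / np.linalg.norm(w)
        ranking = rank_genes(res, k=6)
        assert ranking["gene"].tolist() == ["e", "a", "b", "c", "d", "f"]

    def test_k_exceeding_gene_count_rejected(self):
        res = pls_fit(*random_problem(11, G=5))
        with pytest.raises(ValueError):
            rank_genes(res, k=6)


@pytest.fixture(scope="module")
def geometry():
    return generate_atlas(100, seed=13).centroids


class TestSurrogates:
    def test_deterministic_given_seed(self, geometry):
        x = grf_map(geometry, 50.0, seed=1)
        a = variogram_surrogates(x, geometry, n_surrogates=20, seed=5)
        b = variogram_surrogates(x, geometry, n_surrogates=20, seed=5)
        assert np.array_equal(a.maps, b.maps)

    def test_iid_map_surrogates_match_plain_permutations(self, geometry):
        """For a spatially unstructured source, surrogates behave like
        plain permutations: their variogram slopes sit inside the
        permutation slope distribution."""
        x = np.random.default_rng(2).normal(size=100)
        ens = variogram_surrogates(x, geometry, n_surrogates=30, seed=6)

        def slope(v):
            centers, gamma = empirical_variogram(v, geometry)
            ok = np.isfinite(gamma)
            return np.polyfit(centers[ok], gamma[ok] / gamma[ok].mean(), 1)[0]

        rng = np.random.default_rng(1)
        perm_slopes = [slope(rng.permutation(x)) for _ in range(30)]
        surr_slopes = [slope(m) for m in ens.maps]
        margin = 2 * np.std(perm_slopes)
        assert abs(np.mean(surr_slopes) - np.mean(perm_slopes)) < margin

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            variogram_surrogates(np.arange(12.0), np.ones((12, 3)),
                                 n_surrogates=2, seed=0)

    def test_surrogates_preserve_smooth_variogram(self, geometry):
        """Median (over ensemble) variogram deviation, normalized by the
        source variogram's mean level, stays small for a smooth map."""
        x = grf_map(geometry, 50.0, seed=3)
        ens = variogram_surrogates(x, geometry, n_surrogates=40, seed=7)
        _, g_src = empirical_variogram(x, geometry)
        ok = np.isfinite(g_src)
        scale = g_src[ok].mean()
        devs = [np.nanmean(np.abs(empirical_variogram(m, geometry)[1][ok]
                                  - g_src[ok])) / scale
                for m in ens.maps]
        assert np.median(devs) < 0.25


class TestSurrogatePValue:
    def test_extremes(self):
        coords = generate_atlas(50, seed=14).centroids
        x = grf_map(coords, 60.0, seed=4)
        ens = variogram_surrogates(x, coords, n_surrogates=99, seed=8)
        # identical maps: observed |r| = 1 beats every surrogate
        assert surrogate_pvalue(1.0, ens, x) == pytest.approx(1 / 100)
        # observed r = 0 is below (in magnitude) essentially all surrogates
        assert surrogate_pvalue(0.0, ens, x) == pytest.approx(1.0)

    def test_matches_manual_count(self):
        coords = generate_atlas(40, seed=15).centroids
        x = grf_map(coords, 40.0, seed=5)
        y = grf_map(coords, 40.0, seed=6)
        ens = variogram_surrogates(x, coords, n_surrogates=50, seed=9)
        r_obs = float(np.corrcoef(x, y)[0, 1])
        r_surr = ensemble_correlations(ens, y)
        expected = (1 + (np.abs(r_surr) >= abs(r_obs)).sum()) / 51
        assert surrogate_pvalue(r_obs, ens, y) == pytest.approx(expected)


class TestRiskGenes:
    def test_antiparallel_profile_gives_minus_one(self):
        x, Y = random_problem(16, G=5)
        Y["ACHE"] = -x
        out = adrisk_gene_correlations(x, Y, ["ACHE"])
        assert out["r"].iloc[0] == pytest.approx(-1.0)

    def test_packaged_list_rows_and_missing_log(self):
        x, Y = random_problem(17, G=10)
        Y = Y.rename(columns={Y.columns[0]: "APOE_NOT_IN_LIST"})
        Y["A2M"] = np.random.default_rng(1).normal(size=len(Y))
        Y["MAPT"] = np.random.default_rng(2).normal(size=len(Y))
        out = adrisk_gene_correlations(x, Y, AD_RISK_GENES)
        assert len(out) == 2
        assert len(out.attrs["missing_genes"]) == 26

    def test_no_risk_gene_present_rejected(self):
        x, Y = random_problem(18, G=4)
        with pytest.raises(ValueError):
            adrisk_gene_correlations(x, Y, ["NOTAGENE"])


class TestReplication:
    def test_same_map_gives_unit_weight_correlation(self):
        x, Y = random_problem(19)
        res = pls_fit(x, Y)
        rep = replicate_association(res, x, Y)
        assert rep["weight_correlation"] == pytest.approx(1.0, abs=1e-12)

    def test_small_perturbation_keeps_weights_aligned(self):
        x, Y = random_problem(20, signal=1.0)
        res = pls_fit(x, Y)
        rng = np.random.default_rng(21)
        other = 0.5 * x + pd.Series(0.05 * rng.normal(size=len(x)),
                                    index=x.index)
        rep = replicate_association(res, other, Y)
        assert rep["weight_correlation"] > 0.95
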