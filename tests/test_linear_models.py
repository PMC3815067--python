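"""GLM / mixed-model / compressed mixed-model association engines."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from lofgwas.genodata import MISSING, PhenotypeTable
from lofgwas.linear_models import (
    AssociationTable,
    cmlm_scan,
    compress_kinship,
    default_group_grid,
    glm_scan,
    mlm_scan,
    reml_fit,
)
from lofgwas.relatedness import kinship_vanraden

from conftest import make_genotypes


def random_panel(rng, n=100, m=200):
    dosages = (2.0 * (rng.random((n, m)) < rng.uniform(0.1, 0.9, m))).astype(float)
    y = rng.integers(0, 2, n).astype(float)
    return dosages, y


class TestGlmScan:
    def test_matches_statsmodels_ols(self, rng):
        """Slope p-values agree with an independent OLS fit per SNP."""
        import statsmodels.api as sm

        dosages, y = random_panel(rng, n=40, m=12)
        res = glm_scan(dosages, y)
        for j in range(12):
            fit = sm.OLS(y, sm.add_constant(dosages[:, j])).fit()
            assert res.p_value[j] == pytest.approx(fit.pvalues[1], rel=1e-9)
            assert res.effect[j] == pytest.approx(fit.params[1], rel=1e-9)

    def test_closed_form_simple_regression(self):
        y = np.array([0, 0, 1, 1, 0, 1], dtype=float)
        x = np.array([0, 0, 0, 2, 2, 2], dtype=float)
        res = glm_scan(x[:, None], y)
        # textbook F = r^2 (n-2) / (1 - r^2)
        r = np.corrcoef(x, y)[0, 1]
        F = r**2 * 4 / (1 - r**2)
        from scipy.stats import f as f_dist

        assert res.statistic[0] == pytest.approx(F, rel=1e-12)
        assert res.p_value[0] == pytest.approx(float(f_dist.sf(F, 1, 4)), rel=1e-12)

    def test_monomorphic_snp_missing(self, rng):
        dosages, y = random_panel(rng, n=30, m=5)
        dosages[:, 3] = 2.0
        res = glm_scan(dosages, y)
        assert np.isnan(res.p_value[3])
        assert not np.isnan(np.delete(res.p_value, 3)).any()

    def test_joint_permutation_invariance(self, rng):
        dosages, y = random_panel(rng, n=50, m=20)
        res = glm_scan(dosages, y)
        perm = rng.permutation(50)
        res_p = glm_scan(dosages[perm], y[perm])
        np.testing.assert_allclose(res.p_value, res_p.p_value, rtol=1e-9)

    def test_zero_variance_covariate_dropped(self, rng):
        dosages, y = random_panel(rng, n=40, m=10)
        plain = glm_scan(dosages, y)
        with_const_cov = glm_scan(dosages, y, covariates=np.ones((40, 1)))
        np.testing.assert_allclose(plain.p_value, with_const_cov.p_value, rtol=1e-9)

    def test_too_few_samples_error(self):
        with pytest.raises(ValueError, match="at least"):
            glm_scan(np.array([[0.0], [2.0]]), np.array([0.0, 1.0]))

    def test_genotype_matrix_input_uses_imputed_dosages(self, rng):
        calls = rng.integers(0, 3, size=(30, 6)).astype(np.int8)
        calls[0, 0] = MISSING
        g = make_genotypes(calls)
        y = rng.integers(0, 2, 30).astype(float)
        res = glm_scan(g, y)
        assert list(res.snp_ids) == list(g.snp_ids)
        assert res.n_used[0] == 30


class TestRemlFit:
    def test_identity_kinship_recovers_total_variance(self, rng):
        n = 80
        y = rng.normal(size=n)
        X = np.ones((n, 1))
        vc = reml_fit(y, X, np.eye(n))
        rss = float(((y - y.mean()) ** 2).sum()) / (n - 1)
        assert vc.sigma_g2 + vc.sigma_e2 == pytest.approx(rss, rel=1e-6)

    def test_constant_trait_error(self):
        with pytest.raises(ValueError, match="constant"):
            reml_fit(np.ones(20), np.ones((20, 1)), np.eye(20))

    def test_heritability_recovery_single(self, rng):
        n = 300
        W = 2.0 * (rng.random((n, 500)) < rng.uniform(0.1, 0.9, 500))
        K = kinship_vanraden(W).values
        K /= np.diag(K).mean()
        s, U = np.linalg.eigh(K)
        s = np.maximum(s, 0)
        u = U @ (np.sqrt(s) * rng.normal(size=n))
        y = u + rng.normal(size=n)  # h2 = 0.5 on the kinship scale
        vc = reml_fit(y, np.ones((n, 1)), K)
        assert vc.heritability == pytest.approx(0.5, abs=0.2)

    def test_nonpsd_kinship_rejected(self, rng):
        n = 10
        K = -np.eye(n)
        with pytest.raises(ValueError, match="PSD"):
            reml_fit(rng.normal(size=n), np.ones((n, 1)), K)


class TestMlmScan:
    def test_identity_kinship_equals_glm(self, rng):
        dosages, y = random_panel(rng, n=60, m=80)
        res_glm = glm_scan(dosages, y)
        res_mlm = mlm_scan(dosages, y, np.eye(60))
        d = np.abs(np.log10(res_glm.p_value) - np.log10(res_mlm.p_value))
        assert np.nanmax(d) < 1e-6

    def test_duplicate_snp_columns_identical(self, rng):
        dosages, y = random_panel(rng, n=50, m=10)
        dosages[:, 7] = dosages[:, 2]
        K = kinship_vanraden(dosages + rng.normal(0, 0.01, dosages.shape)).values
        res = mlm_scan(dosages, y, K)
        assert res.p_value[7] == res.p_value[2]

    def test_p3d_close_to_exact(self, rng):
        dosages, y = random_panel(rng, n=80, m=120)
        K = kinship_vanraden(dosages).values
        p3d = mlm_scan(dosages, y, K, mode="p3d")
        exact = mlm_scan(dosages, y, K, mode="exact")
        ok = ~np.isnan(p3d.p_value) & ~np.isnan(exact.p_value)
        rho = spearmanr(-np.log10(p3d.p_value[ok]), -np.log10(exact.p_value[ok])).statistic
        assert rho > 0.99

    def test_exact_ml_never_below_null(self, rng):
        """Adding the SNP fixed effect cannot reduce the maximized likelihood."""
        dosages, y = random_panel(rng, n=60, m=6)
        K = kinship_vanraden(dosages).values
        X0 = np.ones((60, 1))
        null = reml_fit(y, X0, K, method="ml")
        for j in range(6):
            Xj = np.hstack([X0, dosages[:, j : j + 1]])
            full = reml_fit(y, Xj, K, method="ml")
            assert full.reml_loglik >= null.reml_loglik - 1e-8


class TestCompression:
    def test_full_group_count_is_identity(self, rng):
        K = kinship_vanraden(random_panel(rng, n=12, m=60)[0]).values
        plan = compress_kinship(K, 12)
        np.testing.assert_array_equal(plan.group_assignment, np.arange(12))
        np.testing.assert_array_equal(plan.group_kinship, K)

    def test_single_group_is_grand_mean(self, rng):
        K = kinship_vanraden(random_panel(rng, n=9, m=40)[0]).values
        plan = compress_kinship(K, 1)
        assert plan.group_kinship.shape == (1, 1)
        assert plan.group_kinship[0, 0] == pytest.approx(K.mean())

    def test_matches_naive_agglomerative_oracle(self):
        """6-sample average-linkage clustering vs a brute-force implementation."""
        rng = np.random.default_rng(3)
        W = 2.0 * rng.integers(0, 2, (6, 40))
        K = kinship_vanraden(W).values
        plan = compress_kinship(K, 3, linkage="average")

        # naive agglomerative average linkage on d = max(K) - K
        D = K.max() - K
        clusters = [{i} for i in range(6)]
        while len(clusters) > 3:
            best = None
            for a in range(len(clusters)):
                for b in range(a + 1, len(clusters)):
                    d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
                    if best is None or d < best[0]:
                        best = (d, a, b)
            _, a, b = best
            clusters[a] |= clusters[b]
            del clusters[b]
        oracle = {frozenset(c) for c in clusters}
        got = {
            frozenset(np.nonzero(plan.group_assignment == g)[0].tolist())
            for g in range(plan.n_groups)
        }
        assert got == oracle

    def test_group_kinship_is_blockwise_mean(self, rng):
        K = kinship_vanraden(random_panel(rng, n=10, m=50)[0]).values
        plan = compress_kinship(K, 4)
        for a in range(plan.n_groups):
            for b in range(plan.n_groups):
                ia = plan.group_assignment == a
                ib = plan.group_assignment == b
                assert plan.group_kinship[a, b] == pytest.approx(K[np.ix_(ia, ib)].mean())

    def test_invalid_group_count(self, rng):
        K = np.eye(5)
        with pytest.raises(ValueError):
            compress_kinship(K, 0)

    def test_default_grid_span(self):
        grid = default_group_grid(300)
        assert grid[0] == 1 and grid[-1] == 300 and len(grid) <= 10


class TestCmlmScan:
    def test_degenerate_compression_equals_mlm(self, rng):
        dosages, y = random_panel(rng, n=50, m=60)
        K = kinship_vanraden(dosages).values
        mlm = mlm_scan(dosages, y, K)
        cm, plan = cmlm_scan(dosages, y, K, group_grid=[50])
        assert plan.n_groups == 50
        np.testing.assert_array_equal(cm.p_value, mlm.p_value)

    def test_single_group_matches_glm(self, rng):
        dosages, y = random_panel(rng, n=50, m=60)
        K = kinship_vanraden(dosages).values
        res_glm = glm_scan(dosages, y)
        cm, _ = cmlm_scan(dosages, y, K, group_grid=[1])
        d = np.abs(np.log10(res_glm.p_value) - np.log10(cm.p_value))
        assert np.nanmax(d) < 1e-6

    def test_grid_selection_reports_loglik(self, rng):
        dosages, y = random_panel(rng, n=40, m=50)
        K = kinship_vanraden(dosages).values
        res, plan = cmlm_scan(dosages, y, K, group_grid=[2, 10, 40])
        assert plan.reml_loglik_at_fit is not None
        assert res.testable().sum() > 0


class TestAssociationTable:
    def test_round_trip(self, tmp_path, rng):
        dosages, y = random_panel(rng, n=30, m=8)
        dosages[:, 0] = 0.0
        res = glm_scan(dosages, y)
        res.write(tmp_path / "a.tsv")
        back = AssociationTable.read(tmp_path / "a.tsv")
        np.testing.assert_allclose(res.p_value, back.p_value, rtol=1e-12)
        assert back.model_tag == res.model_tag
        assert np.isnan(back.p_value[0])

    def test_rejects_out_of_range_p(self):
        with pytest.raises(ValueError, match="p-values"):
            AssociationTable(
                snp_ids=np.array(["S1_1"], dtype=object),
                chromosome=np.array(["1"], dtype=object),
                position=np.array([1]),
                model_tag="glm",
                p_value=np.array([1.5]),
                statistic=np.array([0.0]),
                effect=np.array([0.0]),
                n_used=np.array([10]),
            )
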