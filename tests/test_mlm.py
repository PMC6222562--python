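import numpy as np
import pytest
from scipy import stats

import gwasroc as g
from gwasroc.mlm import _reml_neg2_profile

from conftest import make_panel_from_matrix


def dense_gls_scan(genotypes, y, K, lam):
    """Independent oracle: per-SNP GLS through explicit matrix inverses.

    H = lam*K + I; beta = (X' H^-1 X)^-1 X' H^-1 y with the residual scale
    re-estimated per marker on n - 2 degrees of freedom.
    """
    n, m = genotypes.shape
    hinv = np.linalg.inv(lam * K + np.eye(n))
    out = np.empty((m, 3))
    for j in range(m):
        x = np.column_stack([np.ones(n), genotypes[:, j]])
        xth = x.T @ hinv
        a = xth @ x
        beta = np.linalg.solve(a, xth @ y)
        r = y - x @ beta
        sigma2 = (r @ hinv @ r) / (n - 2)
        se = np.sqrt(sigma2 * np.linalg.inv(a)[1, 1])
        t = beta[1] / se
        out[j] = beta[1], se, 2 * stats.t.sf(abs(t), n - 2)
    return out


class TestVanRadenKinship:
    def test_two_individual_hand_example(self):
        panel = make_panel_from_matrix([[0.0], [2.0]])
        k = g.vanraden_kinship(panel, 1, seed=0)
        np.testing.assert_allclose(k.values, [[2.0, -2.0], [-2.0, 2.0]])

    def test_identical_genotypes_share_diagonal(self):
        geno = np.tile(np.array([[0.0, 2.0, 2.0, 0.0, 2.0]]), (2, 1))
        geno = np.vstack([geno, [[2.0, 0.0, 2.0, 2.0, 0.0]]])
        panel = make_panel_from_matrix(geno)
        k = g.vanraden_kinship(panel, 5, seed=0)
        assert k.values[0, 1] == pytest.approx(k.values[0, 0])

    def test_matches_double_loop_oracle(self):
        panel = g.simulate_panel(50, 200, seed=41)
        k = g.vanraden_kinship(panel, 200, seed=0)
        geno = panel.genotypes
        f = geno.mean(axis=0) / 2
        denom = 2 * np.sum(f * (1 - f))
        expected = np.empty((50, 50))
        for i in range(50):
            for j in range(50):
                expected[i, j] = np.sum(
                    (geno[i] - 2 * f) * (geno[j] - 2 * f)
                ) / denom
        np.testing.assert_allclose(k.values, expected, atol=1e-10)
        np.testing.assert_allclose(k.values, k.values.T, atol=1e-12)

    def test_positive_semidefinite(self, mid_kinship):
        eigvals = np.linalg.eigvalsh(mid_kinship.values)
        assert eigvals.min() >= -1e-8 * eigvals.max()

    def test_all_monomorphic_raises(self):
        panel = make_panel_from_matrix(np.full((4, 3), 2.0))
        with pytest.raises(ValueError):
            g.vanraden_kinship(panel, 3, seed=0)


class TestFitNullReml:
    def test_pure_noise_gives_low_pseudo_heritability(self, mid_panel, mid_kinship):
        rng = np.random.default_rng(42)
        y = rng.standard_normal(mid_panel.n_ind)
        vc = g.fit_null_reml(y, mid_kinship)
        assert vc.pseudo_heritability < 0.2

    def test_heritability_ordering(self, mid_panel, mid_kinship):
        design = g.SimulationDesign(
            ncl_levels=(1000,), h2_levels=(0.1, 0.9), replicates=1
        )
        traits, _ = g.simulate_trait_set(mid_panel, design, seed=43)
        vcs = {t.h2: g.fit_null_reml(t.phenotypes, mid_kinship) for t in traits}
        assert vcs[0.9].pseudo_heritability > vcs[0.1].pseudo_heritability

    def test_returned_lambda_beats_search_grid(self, mid_panel, mid_kinship):
        design = g.SimulationDesign(ncl_levels=(100,), h2_levels=(0.5,), replicates=1)
        traits, _ = g.simulate_trait_set(mid_panel, design, seed=44)
        y = traits[0].phenotypes
        vc = g.fit_null_reml(y, mid_kinship)
        s, u = mid_kinship.eigen()
        yr, xr = u.T @ y, (u.T @ np.ones(len(y)))[:, None]
        ones = np.ones((len(y), 1))
        _, logdet_xtx = np.linalg.slogdet(ones.T @ ones)
        best = _reml_neg2_profile(vc.lambda_, xr, yr, s, logdet_xtx)[0]
        grid = np.concatenate([[0.0], np.logspace(-5, 5, 100)])
        for lam in grid:
            assert best <= _reml_neg2_profile(lam, xr, yr, s, logdet_xtx)[0] + 1e-9

    def test_zero_variance_phenotype_raises(self, mid_kinship):
        with pytest.raises(ValueError):
            g.fit_null_reml(np.ones(mid_kinship.n_ind), mid_kinship)

    def test_non_finite_phenotype_raises(self, mid_kinship):
        y = np.zeros(mid_kinship.n_ind)
        y[0] = np.nan
        with pytest.raises(ValueError):
            g.fit_null_reml(y, mid_kinship)


class TestScanMarkers:
    def test_identity_covariance_equals_ols(self, tiny_panel):
        rng = np.random.default_rng(45)
        y = rng.standard_normal(tiny_panel.n_ind)
        kin = g.vanraden_kinship(tiny_panel, tiny_panel.n_snp, seed=0)
        vc = g.VarianceComponents(sigma_u2=0.0, sigma_e2=1.0, lambda_=0.0,
                                  reml_loglik=0.0)
        res = g.scan_markers(tiny_panel, y, kin, vc)
        for j in range(tiny_panel.n_snp):
            ols = stats.linregress(tiny_panel.genotypes[:, j], y)
            assert res.p_values[j] == pytest.approx(ols.pvalue, rel=1e-9)
            assert res.beta[j] == pytest.approx(ols.slope, rel=1e-9)

    def test_type_one_error_calibrated(self):
        panel = g.simulate_panel(150, 4000, seed=47)
        panel = g.filter_maf(panel, 0.02)
        kin = g.vanraden_kinship(panel, panel.n_snp, seed=1)
        rng = np.random.default_rng(48)
        y = rng.standard_normal(panel.n_ind)
        res = g.scan_markers(panel, y, kin)
        frac = (res.p_values < 0.05).mean()
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / panel.n_snp)

    def test_huge_effect_snp_has_smallest_p(self, tiny_panel):
        rng = np.random.default_rng(49)
        j_causal = 17
        w = g.standardize_genotypes(tiny_panel, [j_causal])[:, 0]
        y = 20.0 * w + rng.standard_normal(tiny_panel.n_ind)
        kin = g.vanraden_kinship(tiny_panel, tiny_panel.n_snp, seed=2)
        res = g.scan_markers(tiny_panel, y, kin)
        assert np.argmin(res.p_values) == j_causal

    def test_eigen_path_matches_dense_gls(self):
        panel = g.simulate_panel(40, 60, seed=51)
        panel = g.filter_maf(panel, 0.02)
        kin = g.vanraden_kinship(panel, panel.n_snp, seed=3)
        rng = np.random.default_rng(52)
        y = rng.standard_normal(panel.n_ind)
        lam = 0.7
        vc = g.VarianceComponents(sigma_u2=0.7, sigma_e2=1.0, lambda_=lam,
                                  reml_loglik=0.0)
        res = g.scan_markers(panel, y, kin, vc)
        oracle = dense_gls_scan(panel.genotypes, y, kin.values, lam)
        np.testing.assert_allclose(res.beta, oracle[:, 0], rtol=1e-8)
        np.testing.assert_allclose(res.se, oracle[:, 1], rtol=1e-8)
        np.testing.assert_allclose(res.p_values, oracle[:, 2], rtol=1e-6, atol=1e-12)

    def test_p_values_invariant_to_affine_phenotype_rescale(self, mid_panel,
                                                            mid_kinship):
        design = g.SimulationDesign(ncl_levels=(20,), h2_levels=(0.5,), replicates=1)
        traits, _ = g.simulate_trait_set(mid_panel, design, seed=53)
        y = traits[0].phenotypes
        res1 = g.scan_markers(mid_panel, y, mid_kinship)
        res2 = g.scan_markers(mid_panel, 3.0 * y - 7.0, mid_kinship)
        np.testing.assert_allclose(res1.p_values, res2.p_values, rtol=1e-4)

    def test_monomorphic_marker_flagged_not_raised(self):
        geno = np.column_stack(
            [np.full(20, 2.0), np.tile([0.0, 2.0], 10), np.tile([0.0, 0.0, 2.0, 2.0], 5)]
        )
        panel = make_panel_from_matrix(geno)
        rng = np.random.default_rng(54)
        y = rng.standard_normal(20)
        kin = g.KinshipMatrix(values=np.eye(20), snp_count_used=0, method="identity")
        vc = g.VarianceComponents(0.0, 1.0, 0.0, 0.0)
        res = g.scan_markers(panel, y, kin, vc)
        assert res.degenerate[0]
        assert res.p_values[0] == 1.0
        assert not res.degenerate[1:].any()

    def test_per_marker_reml_close_to_p3d(self):
        panel = g.simulate_panel(60, 40, seed=55)
        panel = g.filter_maf(panel, 0.02)
        kin = g.vanraden_kinship(panel, panel.n_snp, seed=4)
        design = g.SimulationDesign(ncl_levels=(5,), h2_levels=(0.6,), replicates=1)
        traits, _ = g.simulate_trait_set(panel, design, seed=56)
        y = traits[0].phenotypes
        fast = g.scan_markers(panel, y, kin)
        slow = g.scan_markers(panel, y, kin, per_marker_reml=True)
        r = np.corrcoef(fast.neg_log10_p, slow.neg_log10_p)[0, 1]
        assert r > 0.95


class TestScanTraitSet:
    def test_matches_single_trait_scan(self, mid_panel, mid_kinship):
        design = g.SimulationDesign(ncl_levels=(10,), h2_levels=(0.4, 0.8),
                                    replicates=1)
        traits, _ = g.simulate_trait_set(mid_panel, design, seed=57)
        batch = g.scan_trait_set(mid_panel, traits, mid_kinship)
        for t, res in zip(traits, batch):
            single = g.scan_markers(mid_panel, t.phenotypes, mid_kinship)
            np.testing.assert_allclose(res.p_values, single.p_values, rtol=1e-8)
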