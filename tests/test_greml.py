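import itertools

import numpy as np
import pytest

from txgc.greml import (
    BivariateFit,
    GRMEigen,
    fit_pair,
    reml_bivariate,
    reml_univariate,
    rg_from_components,
    rg_se_taylor,
    rg_test,
)
from txgc.simulate import SimConfig, simulate_genotypes, simulate_transcript_pair

from helpers import dense_reml_loglik_biv, dense_reml_loglik_uni


def _fit_theta(fit: BivariateFit):
    t = [fit.sigma2_gi, fit.sigma2_gj, fit.sigma_gigj, fit.sigma2_ei, fit.sigma2_ej]
    if fit.sigma_eij is not None:
        t.append(fit.sigma_eij)
    return np.array(t)


class TestUnivariate:
    def test_recovers_true_heritability(self):
        cfg = SimConfig(n_individuals=800, n_snps=2000, n_causal=100, h2_i=0.5, h2_j=0.5, seed=2)
        rng = np.random.default_rng(2)
        G = simulate_genotypes(cfg, rng)
        from txgc.grm import compute_grm

        eig = GRMEigen.from_grm(compute_grm(G))
        h2s = [
            reml_univariate(simulate_transcript_pair(G, cfg, rng)[0], eig).h2
            for _ in range(50)
        ]
        assert 0.45 < np.mean(h2s) < 0.55

    def test_permuted_phenotype_has_no_heritability(self, small_cohort):
        cfg, G, grm, eig = small_cohort
        rng = np.random.default_rng(17)
        h2s = []
        for _ in range(50):
            y, _, _ = simulate_transcript_pair(G, cfg, rng)
            h2s.append(reml_univariate(rng.permutation(y), eig).h2)
        assert np.mean(h2s) < 0.05

    def test_optimum_beats_grid_search(self, tiny_cohort):
        cfg, G, grm, eig = tiny_cohort
        y, _, _ = simulate_transcript_pair(G, cfg)
        fit = reml_univariate(y, eig)
        grid = np.linspace(0.02, 1.5, 11)
        best_grid = max(
            dense_reml_loglik_uni(y, grm.A, sg, se) for sg in grid for se in grid
        )
        assert fit.logL >= best_grid - 1e-6
        # and the optimized value matches the dense evaluation at the optimum
        assert fit.logL == pytest.approx(
            dense_reml_loglik_uni(y, grm.A, fit.sigma2_g, fit.sigma2_e), abs=1e-6
        )

    def test_dimension_mismatch_rejected(self, small_cohort):
        _, _, _, eig = small_cohort
        with pytest.raises(ValueError):
            reml_univariate(np.ones(10), eig)

    def test_identity_like_grm_flags_unreliable_se(self):
        eig = GRMEigen.from_grm(np.eye(60))
        rng = np.random.default_rng(1)
        fit = reml_univariate(rng.normal(size=60), eig)
        assert not fit.se_reliable


class TestBivariate:
    def test_duplicated_trait_hits_plus_one_boundary(self, small_cohort):
        cfg, G, grm, eig = small_cohort
        y, _, _ = simulate_transcript_pair(G, cfg)
        fit = reml_bivariate(y, y.copy(), eig)
        assert fit.boundary_flag
        est = rg_from_components(fit)
        if est.defined:
            assert est.r_G > 0.99

    def test_recovers_genetic_correlation(self):
        cfg = SimConfig(n_individuals=500, n_snps=2000, n_causal=100, h2_i=0.5, h2_j=0.5, r_G=0.8, r_E=0.2, seed=1)
        rng = np.random.default_rng(1)
        G = simulate_genotypes(cfg, rng)
        from txgc.grm import compute_grm

        eig = GRMEigen.from_grm(compute_grm(G))
        rgs = []
        for _ in range(30):
            yi, yj, _ = simulate_transcript_pair(G, cfg, rng)
            rgs.append(rg_from_components(reml_bivariate(yi, yj, eig)).r_G)
        assert 0.75 < np.mean(rgs) < 0.85

    def test_optimum_beats_coarse_grid(self, tiny_cohort):
        cfg, G, grm, eig = tiny_cohort
        yi, yj, _ = simulate_transcript_pair(G, cfg)
        fit = reml_bivariate(yi, yj, eig, include_residual_cov=False)
        var_grid = np.linspace(0.05, 1.2, 5)
        cov_grid = np.linspace(-0.9, 0.9, 7)
        best = -np.inf
        for gi, gj, ei, ej in itertools.product(var_grid, var_grid, var_grid, var_grid):
            for gc in cov_grid:
                if abs(gc) >= np.sqrt(gi * gj):
                    continue
                ll = dense_reml_loglik_biv(yi, yj, grm.A, (gi, gj, gc, ei, ej), include_residual_cov=False)
                best = max(best, ll)
        assert fit.logL >= best - 1e-6

    def test_eigen_loglik_equals_dense(self, tiny_cohort, rng):
        cfg, G, grm, eig = tiny_cohort
        yi, yj, _ = simulate_transcript_pair(G, cfg)
        from txgc.greml import _biv_loglik

        z1, z2 = eig.transform(yi), eig.transform(yj)
        for _ in range(10):
            gi, gj, ei, ej = rng.uniform(0.1, 1.5, 4)
            gc = rng.uniform(-0.9, 0.9) * np.sqrt(gi * gj)
            ec = rng.uniform(-0.9, 0.9) * np.sqrt(ei * ej)
            theta = np.array([gi, gj, gc, ei, ej, ec])
            fast = _biv_loglik(theta, eig.d, eig.c, z1, z2, True)
            dense = dense_reml_loglik_biv(yi, yj, grm.A, theta)
            assert fast == pytest.approx(dense, abs=1e-8)

    def test_loglik_invariant_to_individual_permutation(self, tiny_cohort, rng):
        cfg, G, grm, eig = tiny_cohort
        yi, yj, _ = simulate_transcript_pair(G, cfg)
        fit = reml_bivariate(yi, yj, eig)
        perm = rng.permutation(len(yi))
        eig_p = GRMEigen.from_grm(grm.A[np.ix_(perm, perm)])
        fit_p = reml_bivariate(yi[perm], yj[perm], eig_p)
        assert fit_p.logL == pytest.approx(fit.logL, abs=1e-6)
        assert fit_p.sigma_gigj == pytest.approx(fit.sigma_gigj, abs=1e-4)

    def test_nonconvergence_is_flagged_not_raised(self, small_cohort):
        cfg, G, grm, eig = small_cohort
        y, _, _ = simulate_transcript_pair(G, cfg)
        fit = reml_bivariate(y, -y, eig, max_iter=1)
        assert isinstance(fit, BivariateFit)

    def test_mismatched_lengths_rejected(self, small_cohort):
        _, _, _, eig = small_cohort
        with pytest.raises(ValueError):
            reml_bivariate(np.ones(eig.n), np.ones(eig.n - 1), eig)


def _toy_fit(gi, gj, gc, cov=None, floor=1e-9):
    names = ("sigma2_gi", "sigma2_gj", "sigma_gigj", "sigma2_ei", "sigma2_ej", "sigma_eij")
    C = np.zeros((6, 6)) if cov is None else cov
    return BivariateFit(
        sigma2_gi=gi, sigma2_gj=gj, sigma_gigj=gc,
        sigma2_ei=0.5, sigma2_ej=0.5, sigma_eij=0.0,
        param_names=names, param_cov=C, logL=0.0,
        converged=True, boundary_flag=False, n_iterations=1, var_floor=floor,
    )


class TestRgDerivation:
    def test_zero_covariance_gives_zero_rg(self):
        assert rg_from_components(_toy_fit(0.5, 0.8, 0.0)).r_G == 0.0

    def test_hand_ratio(self):
        est = rg_from_components(_toy_fit(0.5, 0.8, 0.3))
        assert est.r_G == pytest.approx(0.3 / np.sqrt(0.4), abs=1e-4)
        assert est.r_G == pytest.approx(0.4743, abs=1e-4)

    def test_ratio_beyond_one_clamped_and_flagged(self):
        est = rg_from_components(_toy_fit(0.5, 0.5, 0.51))
        assert est.r_G == 1.0
        assert est.boundary_flag

    def test_variance_at_floor_undefined(self):
        est = rg_from_components(_toy_fit(1e-9, 0.5, 0.0))
        assert not est.defined
        assert np.isnan(est.r_G)

    def test_taylor_se_zero_covariance_matrix(self):
        assert rg_se_taylor(_toy_fit(0.5, 0.8, 0.3)) == 0.0

    def test_taylor_se_diagonal_closed_form(self):
        v_c, v_1, v_2 = 0.01, 0.02, 0.03
        C = np.zeros((6, 6))
        C[2, 2], C[0, 0], C[1, 1] = v_c, v_1, v_2
        gi, gj, gc = 0.5, 0.8, 0.3
        fit = _toy_fit(gi, gj, gc, cov=C)
        r = gc / np.sqrt(gi * gj)
        expected = abs(r) * np.sqrt(v_c / gc**2 + v_1 / (4 * gi**2) + v_2 / (4 * gj**2))
        assert rg_se_taylor(fit) == pytest.approx(expected, rel=1e-12)

    def test_taylor_se_calibrated_against_monte_carlo(self):
        cfg = SimConfig(n_individuals=500, n_snps=2000, n_causal=2000, h2_i=0.5, h2_j=0.5, r_G=0.5, r_E=0.2, seed=11)
        rng = np.random.default_rng(11)
        G = simulate_genotypes(cfg, rng)
        from txgc.grm import compute_grm

        eig = GRMEigen.from_grm(compute_grm(G))
        rgs, ses = [], []
        for _ in range(200):
            yi, yj, _ = simulate_transcript_pair(G, cfg, rng)
            est = fit_pair(yi, yj, eig)
            rgs.append(est.r_G)
            ses.append(est.se_rG)
        assert abs(np.mean(ses) - np.std(rgs)) / np.std(rgs) < 0.25


class TestRgTest:
    def test_null_value(self):
        assert rg_test(0.0, 0.3) == (0.0, pytest.approx(1.0))

    def test_hand_chi2(self):
        chi2, p = rg_test(0.5, np.sqrt(0.0625))
        assert chi2 == pytest.approx(4.0)
        assert p == pytest.approx(0.0455, abs=2e-4)

    def test_zero_se_with_nonzero_rg_is_error(self):
        with pytest.raises(ValueError):
            rg_test(0.5, 0.0)
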