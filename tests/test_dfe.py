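"""Selected-SFS engines (PRF and WF transition matrix), gamma-DFE
fitting, class proportions, model comparison, and fragment handling."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import binom as binom_dist

from ratehet.demography import TwoEpochModel, expected_sfs
from ratehet.dfe import (GammaDFE, _sojourn_g, _stationary_density,
                         class_proportions, compare_neutral_vs_gamma,
                         expected_sfs_under_gamma, fit_gamma_dfe,
                         fragmented_loglik, selected_sfs_dynamic,
                         selected_sfs_equilibrium, wf_transition_matrix)
from ratehet.sfs import SFS


class TestPrfEngine:
    def test_neutral_limit_is_theta_over_i(self):
        n = 20
        sfs = selected_sfs_equilibrium(0.0, n, thetaL=100.0)
        i = np.arange(1, n)
        np.testing.assert_allclose(sfs.counts[1:n], 100.0 / i, rtol=1e-8)

    def test_beta_function_identity_selftest(self):
        # Int C(n,i) x^(i-1) (1-x)^(n-i) dx = 1/i through the same
        # quadrature basis used by the engine
        from ratehet.dfe import _quad_basis
        n = 20
        x, w, B = _quad_basis(n)
        vals = B @ (w / x)
        np.testing.assert_allclose(vals, 1.0 / np.arange(1, n), rtol=1e-10)

    @pytest.mark.parametrize("gamma,i", [(5.0, 1), (50.0, 3), (100.0, 1)])
    def test_against_adaptive_quadrature(self, gamma, i):
        n = 20
        engine = selected_sfs_equilibrium(gamma, n, thetaL=1.0).counts[i]
        ref, _ = quad(lambda x: binom_dist.pmf(i, n, x)
                      * _sojourn_g(np.array([x]), gamma)[0], 0, 1,
                      limit=200)
        assert engine == pytest.approx(ref, rel=1e-6)

    def test_strong_selection_enriches_singletons(self):
        n = 20
        neu = selected_sfs_equilibrium(0.0, n).counts[1:n]
        sel = selected_sfs_equilibrium(50.0, n).counts[1:n]
        assert sel[0] / sel.sum() > neu[0] / neu.sum()

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            selected_sfs_equilibrium(-1.0, 20)


class TestWfMatrix:
    def test_rows_sum_to_one(self):
        M = wf_transition_matrix(100, 0.02)
        np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)

    def test_neutral_martingale(self):
        M = wf_transition_matrix(50, 0.0)
        j = np.arange(101)
        np.testing.assert_allclose(M @ j, j, atol=1e-10)

    def test_absorbing_states(self):
        M = wf_transition_matrix(30, 0.1)
        assert M[0, 0] == 1.0
        assert M[-1, -1] == pytest.approx(1.0, abs=1e-12)

    def test_neutral_fixation_probability(self):
        # absorption solve: u = M_interior u + P(-> fixed); u_j = j/2N
        N = 30
        M = wf_transition_matrix(N, 0.0)
        interior = M[1:-1, 1:-1]
        to_fixed = M[1:-1, -1]
        u = np.linalg.solve(np.eye(2 * N - 1) - interior, to_fixed)
        j = np.arange(1, 2 * N)
        np.testing.assert_allclose(u, j / (2 * N), rtol=1e-8)


class TestDynamicEngine:
    def test_neutral_equilibrium_close_to_one_over_i(self):
        n = 20
        wf = selected_sfs_dynamic(None, 0.0, n, N_ref=100,
                                  thetaL=100.0).counts[1:n]
        i = np.arange(1, n)
        assert np.max(np.abs(wf / (100.0 / i) - 1)) < 0.02

    @pytest.mark.parametrize("gamma", [10.0, 50.0])
    def test_converges_to_prf_as_one_over_N(self, gamma):
        n = 20
        prf = selected_sfs_equilibrium(gamma, n, thetaL=100.0).counts[1:n]

        def dev(N_ref):
            wf = selected_sfs_dynamic(None, gamma, n, N_ref=N_ref,
                                      thetaL=100.0).counts[1:n]
            return np.max(np.abs(wf - prf) / prf.sum())

        d200, d400 = dev(200), dev(400)
        assert d400 < 0.65 * d200  # ~1/N_ref convergence
        assert d400 < 0.015

    def test_expansion_raises_singleton_fraction(self):
        n = 20
        eq = selected_sfs_dynamic(None, 0.0, n).counts[1:n]
        ex = selected_sfs_dynamic(TwoEpochModel(1000, 2000, tau=2000),
                                  0.0, n).counts[1:n]
        assert ex[0] / ex.sum() > eq[0] / eq.sum()

    def test_neutral_expansion_matches_coalescent_engine(self):
        # independent route: coalescent branch-time expectations
        n = 20
        model = TwoEpochModel(1000, 2000, tau=2000)
        wf = selected_sfs_dynamic(model, 0.0, n, N_ref=200).counts[1:n]
        coal = expected_sfs(model, n, 1e-8, 1e6).counts[1:n]
        np.testing.assert_allclose(wf / wf.sum(), coal / coal.sum(),
                                   rtol=0.04)


class TestGammaMixture:
    def test_large_beta_approaches_point_mass(self):
        # convergence is limited by the fixed 64-node log grid, so the
        # comparison is on the normalised shape (L1), which shrinks
        # with beta down to the discretisation floor
        n = 20
        point = selected_sfs_equilibrium(20.0, n, thetaL=1.0).counts[1:n]
        pn = point / point.sum()

        def l1(beta):
            mix = expected_sfs_under_gamma(GammaDFE(beta, 20.0), None, n,
                                           engine="prf").counts[1:n]
            return np.abs(mix / mix.sum() - pn).sum(), mix.sum()

        l1_wide, _ = l1(10.0)
        l1_narrow, total = l1(80.0)
        assert l1_narrow < 0.02
        assert l1_narrow < l1_wide
        assert total == pytest.approx(point.sum(), rel=0.05)

    def test_tiny_mean_is_effectively_neutral(self):
        n = 20
        neu = selected_sfs_equilibrium(0.0, n, thetaL=1.0).counts[1:n]
        mix = expected_sfs_under_gamma(GammaDFE(1.0, 1e-3), None, n,
                                       engine="prf").counts[1:n]
        np.testing.assert_allclose(mix, neu, rtol=0.01)

    def test_mixture_nonnegative(self):
        mix = expected_sfs_under_gamma(GammaDFE(0.2, 1e4), None, 20,
                                       engine="prf")
        assert np.all(mix.counts >= 0)


class TestClassProportions:
    def test_exponential_closed_forms(self):
        cp = class_proportions(GammaDFE(1.0, 10.0))
        assert cp.f0 == pytest.approx(1 - np.exp(-0.1), rel=1e-9)
        assert cp.f3 == pytest.approx(np.exp(-10.0), rel=1e-9)

    def test_sum_to_one(self):
        cp = class_proportions(GammaDFE(0.3, 1234.0))
        assert sum(cp.f) == pytest.approx(1.0, abs=1e-12)

    def test_stronger_mean_shifts_mass_upwards(self):
        f0s, f3s = [], []
        for g in (1.0, 10.0, 100.0, 1000.0):
            cp = class_proportions(GammaDFE(0.5, g))
            f0s.append(cp.f0)
            f3s.append(cp.f3)
        assert np.all(np.diff(f0s) < 0)
        assert np.all(np.diff(f3s) > 0)


class TestGammaFit:
    def test_self_consistency(self):
        truth = GammaDFE(0.5, 200.0, theta_sel=500.0)
        data = expected_sfs_under_gamma(truth, None, 100, engine="prf")
        fit = fit_gamma_dfe(None, data, None, engine="prf", n_starts=6,
                            seed=0)
        assert fit.dfe.shape == pytest.approx(0.5, rel=0.02)
        assert fit.dfe.mean_gamma == pytest.approx(200.0, rel=0.02)
        assert fit.dfe.theta_sel == pytest.approx(500.0, rel=0.02)
        assert not fit.boundary_pinned

    def test_noised_recovery_of_class_proportions(self):
        # theta_sel ~ 3.1e4 is the mutation supply of 10 pooled
        # replicates of directly selected exonic sites
        truth = GammaDFE(0.4, 400.0, theta_sel=31000.0)
        true_cp = np.array(class_proportions(truth).f)
        exp = expected_sfs_under_gamma(truth, None, 100, engine="prf")
        rng = np.random.default_rng(11)
        errs = []
        for _ in range(3):
            counts = np.zeros(101)
            counts[1:100] = rng.poisson(exp.counts[1:100])
            fit = fit_gamma_dfe(None, SFS(100, counts), None,
                                engine="prf", n_starts=6, seed=1)
            errs.append(np.abs(np.array(fit.proportions.f) - true_cp))
        assert np.max(errs) < 0.05

    def test_neutral_data_pins_boundary(self):
        n = 100
        counts = np.zeros(n + 1)
        counts[1:n] = np.round(5000.0 / np.arange(1, n))
        fit = fit_gamma_dfe(None, SFS(n, counts), None, engine="prf",
                            n_starts=6, seed=2)
        # a neutral spectrum drives mean_gamma to the lower bound: the
        # reportable "largely neutral" failure mode
        assert fit.proportions.f0 > 0.95 or fit.boundary_pinned


class TestModelComparison:
    def test_gamma_never_worse_than_nested_neutral(self):
        rng = np.random.default_rng(4)
        counts = np.zeros(51)
        counts[1:50] = rng.poisson(200.0 / np.arange(1, 50))
        out = compare_neutral_vs_gamma(SFS(50, counts), None, "prf",
                                       n_starts=4, seed=0)
        assert out["delta_loglik"] >= 0

    def test_strong_selection_rejects_neutral(self):
        truth = GammaDFE(0.5, 500.0, theta_sel=3000.0)
        exp = expected_sfs_under_gamma(truth, None, 50, engine="prf")
        rng = np.random.default_rng(5)
        counts = np.zeros(51)
        counts[1:50] = rng.poisson(exp.counts[1:50])
        out = compare_neutral_vs_gamma(SFS(50, counts), None, "prf",
                                       n_starts=6, seed=0)
        assert out["p_value"] < 0.01

    def test_size_under_neutral_null(self):
        # with the boundary null the 2-d.f. approximation is
        # conservative: the rejection rate should not exceed alpha by
        # more than binomial noise
        n = 30
        i = np.arange(1, n)
        exp = 300.0 / i
        rng = np.random.default_rng(6)
        rejections = 0
        trials = 40
        for _ in range(trials):
            counts = np.zeros(n + 1)
            counts[1:n] = rng.poisson(exp)
            out = compare_neutral_vs_gamma(SFS(n, counts), None, "prf",
                                           n_starts=3, seed=7)
            rejections += out["p_value"] < 0.05
        # binomial 97.5% bound for p = 0.05, 40 trials
        assert rejections <= 6


class TestFragments:
    def test_single_fragment_matches_fit_likelihood(self):
        truth = GammaDFE(0.5, 100.0, theta_sel=800.0)
        exp = expected_sfs_under_gamma(truth, None, 50, engine="prf")
        fit = fit_gamma_dfe(None, exp, None, engine="prf", n_starts=4,
                            seed=0)
        ll = fragmented_loglik([exp], fit.dfe)
        assert ll == pytest.approx(fit.loglik, rel=1e-6)

    def test_homogeneous_split_leaves_optimum_unchanged(self):
        truth = GammaDFE(0.5, 100.0, theta_sel=900.0)
        exp = expected_sfs_under_gamma(truth, None, 30, engine="prf")
        third = SFS(30, exp.counts / 3.0)
        grid = [GammaDFE(b, g) for b in (0.3, 0.5, 0.8)
                for g in (30.0, 100.0, 300.0)]
        whole = [fragmented_loglik([exp], d) for d in grid]
        split = [fragmented_loglik([third] * 3, d) for d in grid]
        assert np.argmax(whole) == np.argmax(split)

    def test_zero_snp_fragment_is_graceful(self):
        exp = expected_sfs_under_gamma(GammaDFE(0.5, 100.0, 500.0), None,
                                       30, engine="prf")
        empty = SFS(30, np.zeros(31))
        ll_with = fragmented_loglik([exp, empty], GammaDFE(0.5, 100.0))
        ll_without = fragmented_loglik([exp], GammaDFE(0.5, 100.0))
        assert ll_with == pytest.approx(ll_without, rel=1e-12)

    def test_empty_fragment_list_rejected(self):
        with pytest.raises(ValueError):
            fragmented_loglik([], GammaDFE(1.0, 1.0))
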