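"""Unit tests of the MCMC conditionals against closed forms, quadrature
oracles and exhaustive enumeration on tiny instances."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from hbggm.core import inner_products, is_positive_definite, standardise_panel
from hbggm.sampler import (
    SamplerConfig,
    column_log_evidence,
    compute_upsilon,
    draw_column_strengths,
    draw_nu,
    gibbs_sweep,
    run_sampler,
    update_a,
    update_chi,
    update_lambda,
    update_mu_column,
    update_sigma,
    update_z_column,
    _init_state,
)
from hbggm.priors import default_hyperconstants
from hbggm.simulate import SimulationSpec, circle_precision, generate

from conftest import random_pd


class TestDrawNu:
    def test_mean_of_gamma(self, rng):
        draws = draw_nu(np.full(100_000, 2.0), 1.0, 1.0, rng)
        assert draws.mean() == pytest.approx(2.0, abs=0.02)

    def test_distribution_matches_gamma_cdf(self, rng):
        draws = draw_nu(np.full(100_000, 7.0), 2.0, 0.5, rng)
        ks = stats.kstest(draws, stats.gamma(a=4.5, scale=1 / 1.25).cdf).statistic
        assert ks < 0.01

    def test_positivity_and_rate_check(self, rng):
        assert np.all(draw_nu(np.full(1000, 3.0), 0.1, 0.1, rng) > 0)
        with pytest.raises(ValueError):
            draw_nu(2.0, -1.0, 0.5, rng)


class TestUpsilon:
    def test_unit_scale_is_identity_map(self):
        M = np.linalg.inv(random_pd(4, np.random.default_rng(0)))
        np.testing.assert_allclose(compute_upsilon(0.5, 0.5, M), M)

    def test_scaling_linearity(self):
        M = np.eye(3)
        np.testing.assert_allclose(compute_upsilon(2.0, 2.0, M), 2 * compute_upsilon(1.0, 1.0, M))

    def test_circle_column_against_direct_inversion(self, circle6):
        Om11 = circle6[:5, :5]
        ups = compute_upsilon(1.0, 0.0, np.linalg.inv(Om11))
        np.testing.assert_allclose(ups, np.linalg.inv(Om11), atol=1e-12)


class TestColumnStrengths:
    def test_spike_pattern_zeroes_exactly(self, rng):
        u = draw_column_strengths(np.eye(3)[None], np.zeros((1, 3)), np.zeros(3),
                                  np.ones(3), np.zeros(3), rng)
        assert np.all(u == 0.0)

    def test_no_data_limit_recovers_slab(self):
        # Upsilon -> 0, S12 = 0: draws are N(mu, sigma^2) per included entry
        rng = np.random.default_rng(2)
        n = 50_000
        Ups = np.zeros((n, 2, 2))
        u = draw_column_strengths(Ups, np.zeros((n, 2)), np.array([0.4, -0.2]),
                                  np.array([0.5, 1.5]), np.ones(2), rng)
        np.testing.assert_allclose(u.mean(axis=0), [0.4, -0.2], atol=0.02)
        np.testing.assert_allclose(u.std(axis=0), [0.5, 1.5], rtol=0.02)

    def test_matches_analytic_gaussian_posterior(self):
        # fixed small data: empirical moments vs the conjugate closed form
        rng = np.random.default_rng(3)
        Ups1 = random_pd(2, np.random.default_rng(9))
        S12_1 = np.array([0.8, -0.5])
        mu, sig = np.array([0.1, 0.2]), np.array([0.6, 0.9])
        n = 100_000
        u = draw_column_strengths(np.tile(Ups1, (n, 1, 1)), np.tile(S12_1, (n, 1)),
                                  mu, sig, np.ones(2), rng)
        Q = Ups1 + np.diag(1 / sig**2)
        mean = np.linalg.solve(Q, -S12_1 + mu / sig**2)
        cov = np.linalg.inv(Q)
        se = np.sqrt(np.diag(cov) / n)
        np.testing.assert_array_less(np.abs(u.mean(axis=0) - mean), 2.5 * se)
        np.testing.assert_allclose(np.cov(u.T), cov, rtol=0.03)


def gauss_hermite_log_evidence(Ups, S12, z, sigma12, chi, n_nodes=70):
    """Independent oracle: nested Gauss-Hermite quadrature over (u_s, mu)."""
    from itertools import product

    idx = np.flatnonzero(z)
    k = idx.size
    if k == 0:
        return 0.0
    x, w = np.polynomial.hermite_e.hermegauss(n_nodes)
    norm = (2 * np.pi) ** (k / 2)
    grid = np.array(list(product(x, repeat=k)))
    gw = np.prod(np.array(list(product(w, repeat=k))), axis=1) / norm
    sig = np.asarray(sigma12, float)[idx]
    mu_nodes = grid * chi
    inner = np.ones((len(grid), len(S12)))
    for s in range(len(S12)):
        U = Ups[s][np.ix_(idx, idx)]
        c = S12[s, idx]
        u = mu_nodes[:, None, :] + (grid * sig)[None, :, :]
        f = np.exp(-0.5 * np.einsum("abi,ij,abj->ab", u, U, u) - u @ c)
        inner[:, s] = f @ gw
    return float(np.log(np.prod(inner, axis=1) @ gw))


class TestColumnEvidence:
    def _column_data(self, seed=4, n_subj=2, q=2):
        rng = np.random.default_rng(seed)
        Ups = np.stack([0.8 * random_pd(q, rng) for _ in range(n_subj)])
        S12 = rng.normal(size=(n_subj, q))
        return Ups, S12

    def test_empty_pattern_is_reference_zero(self):
        Ups, S12 = self._column_data()
        assert column_log_evidence(Ups, S12, np.zeros(2), np.ones(2), 0.7) == 0.0

    @pytest.mark.parametrize("z", [(1, 0), (0, 1), (1, 1)])
    def test_quadrature_oracle_agreement(self, z):
        Ups, S12 = self._column_data()
        sigma12 = np.array([0.6, 0.4])
        a = column_log_evidence(Ups, S12, np.array(z), sigma12, 0.7)
        b = gauss_hermite_log_evidence(Ups, S12, np.array(z), sigma12, 0.7)
        assert a == pytest.approx(b, abs=1e-6)

    def test_vanishing_slab_is_free_edge(self):
        # sigma -> 0 with mu centred at zero collapses the slab onto the spike
        Ups, S12 = self._column_data()
        base = column_log_evidence(Ups, S12, np.array([1, 0]), np.array([0.5, 1e-7]), 1e-7)
        # chi tiny too so the added edge's mean is pinned at zero
        both = column_log_evidence(Ups, S12, np.array([1, 1]), np.array([0.5, 1e-7]), 1e-7)
        # evidence contributions of the pinned edge cancel in the difference
        free_edge = both - base
        assert abs(free_edge) < 1e-3


class TestUpdateZ:
    def test_full_prior_rejects_removals(self, rng):
        Ups, S12 = TestColumnEvidence()._column_data()
        z = np.ones(2, dtype=int)
        for _ in range(50):
            z, _ = update_z_column(Ups, S12, z, np.ones(2), 0.7, 1.0, rng)
        assert np.all(z == 1)

    def test_two_node_inclusion_matches_enumeration(self):
        # p=2 column: single indicator; exact 2-state posterior by enumeration
        rng = np.random.default_rng(6)
        Ups = np.stack([np.array([[2.0]]), np.array([[1.5]])])
        S12 = np.array([[1.2], [0.9]])
        sigma12, chi, a = np.array([0.5]), 0.7, 0.4
        logE1 = column_log_evidence(Ups, S12, np.ones(1), sigma12, chi)
        odds = math.exp(logE1) * a / (1 - a)
        target = odds / (1 + odds)
        z = np.ones(1, dtype=int)
        hits = 0
        n_iter = 20_000
        for _ in range(n_iter):
            z, _ = update_z_column(Ups, S12, z, sigma12, chi, a, rng)
            hits += int(z[0])
        assert hits / n_iter == pytest.approx(target, abs=0.02)


class TestUpdateMu:
    def test_conjugate_posterior_single_subject(self):
        rng = np.random.default_rng(7)
        draws = np.array([
            update_mu_column(np.array([[2.0]]), np.ones(1), 1.0, np.ones(1), rng)[0]
            for _ in range(20_000)
        ])
        assert draws.mean() == pytest.approx(1.0, abs=0.02)
        assert draws.var() == pytest.approx(0.5, rel=0.05)

    def test_diffuse_group_prior_recovers_sample_mean(self, rng):
        u = np.array([[0.3], [0.5], [0.7]])
        draws = np.array([
            update_mu_column(u, np.array([0.01]), 1e6, np.ones(1), rng)[0]
            for _ in range(2000)
        ])
        assert draws.mean() == pytest.approx(0.5, abs=0.001)

    def test_matches_quadrature_posterior(self):
        # posterior ∝ N(mu; 0, chi^2) * prod_s N(u_s; mu, sigma^2)
        u = np.array([[0.4], [0.9]])
        sigma, chi = 0.6, 0.8
        unnorm = lambda m: (
            stats.norm.pdf(m, 0, chi) * np.prod(stats.norm.pdf(u[:, 0], m, sigma))
        )
        Zc, _ = integrate.quad(unnorm, -10, 10)
        mean_q, _ = integrate.quad(lambda m: m * unnorm(m) / Zc, -10, 10)
        rng = np.random.default_rng(8)
        draws = np.array([
            update_mu_column(u, np.array([sigma]), chi, np.ones(1), rng)[0]
            for _ in range(20_000)
        ])
        se = draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - mean_q) < 3 * se

    def test_excluded_edges_refresh_from_prior(self, rng):
        draws = np.array([
            update_mu_column(np.array([[5.0]]), np.ones(1), 0.3, np.zeros(1), rng)[0]
            for _ in range(5000)
        ])
        assert abs(draws.mean()) < 0.02
        assert draws.std() == pytest.approx(0.3, rel=0.05)


class TestUpdateSigma:
    def test_prior_recovery_with_no_included_edges(self):
        from hbggm.priors import default_hyperconstants

        rng = np.random.default_rng(9)
        c = default_hyperconstants()
        draws = np.array([
            update_sigma(np.ones(1), np.zeros((1, 1)), np.zeros(1), np.zeros(1),
                         c, rng, 0.1)[0][0]
            for _ in range(20_000)
        ])
        logs = np.log(draws)
        assert logs.mean() == pytest.approx(np.log(0.5), abs=0.02)
        assert logs.std() == pytest.approx(1.0, rel=0.03)

    def test_posterior_concentrates_near_true_scale(self):
        from hbggm.priors import default_hyperconstants

        rng = np.random.default_rng(10)
        c = default_hyperconstants()
        u = rng.normal(0.0, 0.2, size=(50, 1))
        sigma = np.array([0.5])
        kept = []
        for t in range(4000):
            sigma, acc = update_sigma(sigma, u, np.zeros(1), np.ones(1), c, rng, 0.15)
            if t >= 1000:
                kept.append(sigma[0])
        # 1-D quadrature posterior mean as the oracle
        ss = float((u**2).sum())
        def unnorm(s):
            return (
                stats.lognorm(s=1.0, scale=0.5).pdf(s)
                * s ** (-50) * np.exp(-ss / (2 * s**2))
            )
        Zc, _ = integrate.quad(unnorm, 1e-3, 5)
        mean_q, _ = integrate.quad(lambda s: s * unnorm(s) / Zc, 1e-3, 5)
        assert abs(np.mean(kept) - mean_q) < 0.05
        assert abs(np.mean(kept) - 0.2) < 0.05

    def test_acceptance_rate_sane(self):
        from hbggm.priors import default_hyperconstants

        rng = np.random.default_rng(11)
        c = default_hyperconstants()
        u = rng.normal(0.0, 0.3, size=(10, 4))
        sigma = np.full(4, 0.5)
        accs = []
        for _ in range(500):
            sigma, acc = update_sigma(sigma, u, np.zeros(4), np.ones(4), c, rng, 0.1)
            accs.append(acc)
        assert 0.1 < np.mean(accs) < 0.9


class TestUpdateChiLambdaA:
    def test_chi_likelihood_dominance(self, rng):
        mu = np.full(1000, 0.3)
        chis = np.array([update_chi(mu, 1.0, 0.7, rng)[0] for _ in range(500)])
        assert chis.mean() == pytest.approx(0.3, abs=0.02)
        assert np.all(chis > 0)

    def test_lambda_conjugate_moments_and_quadrature(self, rng):
        draws = update_lambda(np.tile([1.0, 1.0], (100_000, 1)),
                              default_hyperconstants(),
                              rng)
        assert draws.mean() == pytest.approx(7 / 3, rel=0.01)
        # independent quadrature of prior x likelihood for p=2, diag (1,1)
        unnorm = lambda lam: lam ** (1 / 3 - 1) * (lam / 2) ** 2 * np.exp(-lam)
        Zc, _ = integrate.quad(unnorm, 0, 60)
        mean_q, _ = integrate.quad(lambda l: l * unnorm(l) / Zc, 0, 60)
        assert draws.mean() == pytest.approx(mean_q, rel=0.01)

    def test_lambda_scaling(self, rng):
        a = update_lambda(np.tile([1.0, 1.0], (50_000, 1)),
                          default_hyperconstants(), rng)
        b = update_lambda(np.tile([2.0, 2.0], (50_000, 1)),
                          default_hyperconstants(), rng)
        assert b.mean() == pytest.approx(a.mean() / 2, rel=0.02)

    def test_a_beta_moments(self, rng):
        from hbggm.priors import default_hyperconstants

        c = default_hyperconstants()
        empty = np.array([update_a(np.zeros((4, 4)), c, rng) for _ in range(50_000)])
        assert empty.mean() == pytest.approx(6 / 18, abs=0.005)
        full = np.ones((4, 4)) - np.eye(4)
        full_draws = np.array([update_a(full, c, rng) for _ in range(50_000)])
        assert full_draws.mean() == pytest.approx(12 / 18, abs=0.005)


class TestSweepAndRun:
    def _tiny(self, seed=0):
        spec = SimulationSpec("t", n_subjects=2, p=3, n_s=40)
        return generate(spec, seed)

    def test_single_sweep_preserves_pd(self):
        panel, _ = self._tiny()
        cfg = SamplerConfig(model="strong", n_samples=1, n_warmup=0, thin=1, seed=0)
        panel = standardise_panel(panel, unit_variance=True)
        ips = inner_products(panel)
        S, n_s = np.asarray(ips.S), np.asarray(ips.n_s, float)
        state = _init_state(S, n_s, cfg)
        state = gibbs_sweep(state, S, n_s, cfg, np.random.default_rng(0))
        for om in state.Omega:
            assert is_positive_definite(om)

    def test_seed_determinism(self):
        panel, _ = self._tiny()
        cfg = SamplerConfig(model="strong", n_samples=50, n_warmup=20, thin=5, seed=9)
        a = run_sampler(panel, cfg)
        b = run_sampler(panel, cfg)
        np.testing.assert_array_equal(a.Omega, b.Omega)
        np.testing.assert_array_equal(a.Z, b.Z)

    def test_weak_model_tracks_mle_at_large_n(self):
        spec = SimulationSpec("t", n_subjects=1, p=3, n_s=5000)
        panel, _ = generate(spec, 1)
        cfg = SamplerConfig(model="weak", n_samples=800, n_warmup=300, thin=10, seed=2)
        draws = run_sampler(panel, cfg)
        std = standardise_panel(panel, unit_variance=True)
        S = np.asarray(inner_products(std).S[0])
        mle = np.linalg.inv(S / 5000)
        post = draws.Omega.reshape(-1, 1, 3, 3).mean(axis=0)[0]
        rel = np.linalg.norm(post - mle) / np.linalg.norm(mle)
        assert rel < 0.05

    def test_more_nodes_than_samples_warns(self):
        rng = np.random.default_rng(0)
        from hbggm.core import TimeSeriesPanel

        panel = TimeSeriesPanel([rng.normal(size=(8, 3))])
        cfg = SamplerConfig(model="weak", n_samples=10, n_warmup=5, thin=1, seed=0)
        with pytest.warns(UserWarning, match="more nodes"):
            run_sampler(panel, cfg)

    def test_nonfinite_data_rejected(self):
        from hbggm.core import TimeSeriesPanel

        y = np.ones((3, 10))
        y[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            run_sampler(TimeSeriesPanel([y]), SamplerConfig(n_samples=1, n_warmup=0))

    def test_posterior_draws_summaries(self):
        panel, _ = self._tiny()
        cfg = SamplerConfig(model="strong", n_samples=60, n_warmup=30, thin=6, seed=3)
        d = run_sampler(panel, cfg)
        probs = d.edge_probabilities()
        assert np.all((probs >= 0) & (probs <= 1))
        lo, hi = d.credible_interval(0.9)
        pm = d.subject_partial_corr_mean()
        assert lo.shape == pm.shape
        diag = d.diagnostics()
        assert "rhat_loglik" in diag

    def test_archive_round_trip(self, tmp_path):
        panel, _ = self._tiny()
        cfg = SamplerConfig(model="strong", n_samples=20, n_warmup=10, thin=2, seed=4)
        d = run_sampler(panel, cfg)
        d.save(tmp_path / "draws")
        from hbggm.sampler import PosteriorDraws

        back = PosteriorDraws.load(tmp_path / "draws")
        np.testing.assert_array_equal(back.Omega, d.Omega)
        np.testing.assert_array_equal(back.pcorr_mean, d.pcorr_mean)
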