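"""Full-conditional correctness, likelihood evaluation, and sampler behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import gamma as gamma_dist
from scipy.stats import invgamma, kstest, nbinom, norm

from bmnb import (
    CountPanel,
    CovarianceSet,
    PriorSpec,
    build_design,
    nb_log_pmf,
    run_gibbs,
)
from bmnb.model import BMNBSampler

from conftest import balanced_panel, make_rng


def make_sampler(I=1, J=2, K=1, n=4, counts=None, seed=0, prior=None, **kw):
    panel = balanced_panel(I=I, J=J, K=K, n=n, counts=counts, seed=seed)
    design = build_design(panel, include_blocks=False)
    covset = CovarianceSet.from_g1(np.eye(J), I)
    prior = prior or PriorSpec.default(design.X.shape[1])
    return BMNBSampler(panel, design, covset, prior, **kw), panel


class TestNBLogPmf:
    def test_closed_form_values(self):
        assert nb_log_pmf(0, 0.0, 1.0) == pytest.approx(np.log(0.5))
        assert nb_log_pmf(2, 0.0, 2.0) == pytest.approx(np.log(3.0 / 16.0))

    def test_agrees_with_standard_parameterization(self):
        """Same pmf as NB with mean mu = r·e^{eta*} (p = r/(r+mu))."""
        rng = make_rng(3)
        for _ in range(20):
            y = rng.integers(0, 30)
            eta, r = rng.normal(), rng.gamma(3.0)
            mu = r * np.exp(eta)
            ref = nbinom.logpmf(y, r, r / (r + mu))
            assert nb_log_pmf(y, eta, r) == pytest.approx(ref, rel=1e-10)

    def test_mean_variance_relation(self):
        """Simulated NB counts show Var = mu + mu^2/r."""
        rng = make_rng(4)
        r, mu = 5.0, 7.0
        y = rng.negative_binomial(r, r / (r + mu), size=200_000)
        assert y.mean() == pytest.approx(mu, rel=0.02)
        assert y.var() == pytest.approx(mu + mu**2 / r, rel=0.03)

    def test_extreme_eta_is_finite(self):
        assert np.isfinite(nb_log_pmf(3, 200.0, 2.0))
        assert np.isfinite(nb_log_pmf(3, -200.0, 2.0))

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            nb_log_pmf(-1, 0.0, 1.0)
        with pytest.raises(ValueError):
            nb_log_pmf(1, 0.0, 0.0)


class TestConditionalOracles:
    """Each Gibbs update, all else held fixed, reproduces its closed-form
    conditional distribution (KS test, alpha = 0.01, 10^4 draws)."""

    N = 10_000

    def test_beta_conditional_is_normal(self):
        sampler, panel = make_sampler(I=1, J=2, n=4, seed=5)
        rng = make_rng(42)
        st0 = sampler.init_state(rng)
        st0.omega = rng.gamma(2.0, size=panel.n_T)  # arbitrary fixed weights
        st0.b1 = np.array([0.3, -0.2])
        st0.r = 2.0
        # closed form computed with scalar arithmetic (p = 1, X = 1-column)
        prec0 = 1.0 / sampler.prior.Sigma0[0, 0]
        kappa = 0.5 * (panel.y - st0.r)
        zb = st0.b1[panel.line_idx] + st0.b2[panel.cell_idx]
        a = prec0 + st0.omega.sum()
        mean = (np.sum(kappa - st0.omega * zb)) / a
        draws = np.empty(self.N)
        for i in range(self.N):
            st = st0.copy()
            sampler.update_beta(st, rng)
            draws[i] = st.beta_star[0]
        assert kstest(draws, norm(mean, 1.0 / np.sqrt(a)).cdf).pvalue > 0.01

    def test_b1_marginal_conditional_is_normal(self):
        sampler, panel = make_sampler(I=2, J=2, n=3, seed=6)
        rng = make_rng(43)
        st0 = sampler.init_state(rng)
        st0.omega = rng.gamma(2.0, size=panel.n_T)
        st0.beta_star = np.array([0.5, -0.5])
        st0.sigma_b12 = 0.7
        kappa = 0.5 * (panel.y - st0.r)
        eta1 = sampler.X @ st0.beta_star + st0.b2[panel.cell_idx]
        s = np.bincount(panel.line_idx, weights=st0.omega, minlength=2)
        rhs = np.bincount(panel.line_idx, weights=kappa - st0.omega * eta1, minlength=2)
        F = np.linalg.inv(np.eye(2) / st0.sigma_b12 + np.diag(s))
        mean = F @ rhs
        draws = np.empty(self.N)
        for i in range(self.N):
            st = st0.copy()
            sampler.update_b1(st, rng)
            draws[i] = st.b1[0]
        assert kstest(draws, norm(mean[0], np.sqrt(F[0, 0])).cdf).pvalue > 0.01

    def test_b2_blocks_are_independent_across_environments(self):
        """With diagonal Dω and block-diagonal G2, the cross-environment
        posterior covariance of b2 is zero."""
        sampler, panel = make_sampler(I=2, J=2, n=3, seed=7)
        rng = make_rng(44)
        st0 = sampler.init_state(rng)
        st0.omega = rng.gamma(2.0, size=panel.n_T)
        draws = np.empty((self.N, 4))
        for i in range(self.N):
            st = st0.copy()
            sampler.update_b2(st, rng)
            draws[i] = st.b2
        C = np.cov(draws.T)
        cross = C[:2, 2:]
        se = np.sqrt(np.outer(np.diag(C)[:2], np.diag(C)[2:]) / self.N)
        assert np.all(np.abs(cross) < 5 * se)

    def test_sigma_b_conditional_is_scaled_inv_chi2(self):
        sampler, panel = make_sampler(I=1, J=2, n=4, seed=8)
        rng = make_rng(45)
        st0 = sampler.init_state(rng)
        st0.b1 = np.array([0.8, -0.4])
        quad = float(st0.b1 @ st0.b1)  # G1 = I
        nu, S, J = sampler.prior.nu_b1, sampler.prior.S_b1, 2
        df, scale = nu + J, (quad + nu * S) / (nu + J)
        draws = np.empty(self.N)
        for i in range(self.N):
            st = st0.copy()
            sampler.update_sigma_b(st, 1, rng)
            draws[i] = st.sigma_b12
        # scaled-inv-chi2(df, scale) == invgamma(df/2, scale=df*scale/2)
        assert kstest(draws, invgamma(df / 2, scale=df * scale / 2).cdf).pvalue > 0.01

    def test_sigma_b_scale_arithmetic(self):
        """Degrees of freedom and scale follow (b'G^{-1}b + nu*S)/(nu + n_b)."""
        quad, nu, S, J = 10.0, 3.0, 0.001, 20
        assert nu + J == 23
        assert (quad + nu * S) / (nu + J) == pytest.approx(0.4349130434782609)

    def test_sigma_beta_conditional_is_scaled_inv_chi2(self):
        prior = PriorSpec(
            beta0=np.zeros(1), Sigma0=np.eye(1) * 2.0, nu_beta=4.0, S_beta=0.5
        )
        sampler, panel = make_sampler(I=1, J=2, n=4, seed=9, prior=prior)
        rng = make_rng(46)
        st0 = sampler.init_state(rng)
        st0.beta_star = np.array([1.2])
        quad = 1.2**2 / 2.0
        df = 4.0 + 1
        scale = (quad + 4.0 * 0.5) / df
        draws = np.empty(self.N)
        for i in range(self.N):
            st = st0.copy()
            sampler.update_sigma_beta(st, rng)
            draws[i] = st.sigma_beta2
        assert kstest(draws, invgamma(df / 2, scale=df * scale / 2).cdf).pvalue > 0.01

    def test_r_conditional_is_gamma_for_binary_counts(self):
        """With all counts in {0, 1} the CRT draw is deterministic (L = y),
        so r | ELSE is exactly Gamma(a0 + sum(y), rate b0 - sum(log(1-pi)))."""
        counts = [0, 1, 1, 0, 1, 0, 1, 1]
        sampler, panel = make_sampler(I=1, J=2, n=4, counts=list(counts))
        rng = make_rng(47)
        st0 = sampler.init_state(rng)
        st0.beta_star = np.array([0.3])
        eta = sampler.eta_star(st0)
        shape = sampler.prior.a0 + sum(counts)
        rate = sampler.prior.b0 + np.logaddexp(0.0, eta).sum()
        draws = np.empty(self.N)
        for i in range(self.N):
            st = st0.copy()
            sampler.update_r(st, rng)
            draws[i] = st.r
        assert kstest(draws, gamma_dist(shape, scale=1.0 / rate).cdf).pvalue > 0.01

    def test_omega_conditional_moments(self):
        """omega update draws PG(y + r, eta*): empirical mean of repeated
        updates matches the PG moment formula per record."""
        from bmnb.augmentation import pg_mean

        counts = [0, 2, 5, 1, 3, 0, 4, 2]
        sampler, panel = make_sampler(I=1, J=2, n=4, counts=list(counts))
        rng = make_rng(48)
        st0 = sampler.init_state(rng)
        st0.beta_star = np.array([0.4])
        st0.b1 = np.array([0.2, -0.6])
        st0.r = 1.0
        eta = sampler.eta_star(st0)
        acc = np.zeros(panel.n_T)
        acc2 = np.zeros(panel.n_T)
        reps = 4000
        for _ in range(reps):
            st = st0.copy()
            sampler.update_omega(st, rng)
            acc += st.omega
            acc2 += st.omega**2
        emp = acc / reps
        se = np.sqrt((acc2 / reps - emp**2) / reps)
        expect = pg_mean(panel.y + st0.r, eta)
        assert np.all(np.abs(emp - expect) < 4 * se)


class TestShrinkage:
    def test_b1_shrinks_to_zero_with_tiny_prior_variance(self):
        sampler, panel = make_sampler(I=1, J=2, n=4, fixed_sigma_b1=1e-10)
        rng = make_rng(50)
        st = sampler.init_state(rng)
        st.omega = np.full(panel.n_T, 1.0)
        sampler.update_b1(st, rng)
        assert np.abs(st.b1).max() < 1e-3

    def test_beta_pulled_to_prior_mean_under_enormous_precision(self):
        prior = PriorSpec(beta0=np.array([2.0]), Sigma0=np.eye(1) * 1e-12)
        sampler, panel = make_sampler(I=1, J=2, n=4, prior=prior)
        rng = make_rng(51)
        st = sampler.init_state(rng)
        st.omega = np.full(panel.n_T, 1.0)
        sampler.update_beta(st, rng)
        assert st.beta_star[0] == pytest.approx(2.0, abs=1e-3)


class TestRunGibbs:
    def test_single_retained_draw_edge(self):
        panel = balanced_panel(I=2, J=2, K=1, n=2)
        design = build_design(panel, include_blocks=False)
        covset = CovarianceSet.from_g1(np.eye(2), 2)
        ch = run_gibbs(
            panel, design, covset, PriorSpec.default(2), 3, 2, make_rng(0)
        )
        assert ch.n_draws == 1
        assert np.isfinite(ch.loglik).all()
        assert ch.beta.shape == (1, 2)

    def test_identical_seed_gives_bitwise_identical_chains(self):
        panel = balanced_panel(I=2, J=3, K=1, n=2)
        design = build_design(panel, include_blocks=False)
        covset = CovarianceSet.from_g1(np.eye(3), 2)
        runs = [
            run_gibbs(panel, design, covset, PriorSpec.default(2), 60, 20, make_rng(99))
            for _ in range(2)
        ]
        np.testing.assert_array_equal(runs[0].beta_star, runs[1].beta_star)
        np.testing.assert_array_equal(runs[0].r, runs[1].r)
        np.testing.assert_array_equal(runs[0].b2, runs[1].b2)

    def test_back_transform_applies_log_r_to_environment_coefficients(self):
        panel = balanced_panel(I=2, J=2, K=2, n=2)
        design = build_design(panel, include_blocks=True)
        covset = CovarianceSet.from_g1(np.eye(2), 2)
        ch = run_gibbs(panel, design, covset, PriorSpec.default(6), 30, 10, make_rng(3))
        np.testing.assert_allclose(
            ch.beta[:, :2], ch.beta_star[:, :2] + np.log(ch.r)[:, None]
        )
        np.testing.assert_array_equal(ch.beta[:, 2:], ch.beta_star[:, 2:])

    def test_fixed_r_skips_dispersion_and_stays_constant(self):
        panel = balanced_panel(I=1, J=2, K=1, n=4)
        design = build_design(panel, include_blocks=False)
        covset = CovarianceSet.from_g1(np.eye(2), 1)
        ch = run_gibbs(
            panel, design, covset, PriorSpec.default(1), 50, 10, make_rng(4),
            fixed_r=1000.0,
        )
        assert (ch.r == 1000.0).all()

    def test_flat_prior_drops_redundant_block_columns(self):
        panel = balanced_panel(I=2, J=2, K=2, n=2)
        design = build_design(panel, include_blocks=True)
        covset = CovarianceSet.from_g1(np.eye(2), 2)
        prior = PriorSpec(
            beta0=np.zeros(4), Sigma0=np.eye(4), flat_beta=True
        )  # p reduced from 6 to 4
        ch = run_gibbs(panel, design, covset, prior, 30, 10, make_rng(5))
        assert ch.beta_star.shape[1] == 4
        assert np.isfinite(ch.beta_star).all()

    def test_exchangeable_lines_have_exchangeable_posterior_means(self):
        """Balanced data with identical counts across lines: posterior means
        of b1 agree across lines within Monte-Carlo error (symmetry)."""
        counts = [3, 1, 2, 4] * 4
        panel = balanced_panel(I=1, J=2, K=1, n=8, counts=list(counts[:16]))
        # identical per-line count multisets by construction
        design = build_design(panel, include_blocks=False)
        covset = CovarianceSet.from_g1(np.eye(2), 1)
        ch = run_gibbs(
            panel, design, covset, PriorSpec.default(1), 3000, 500, make_rng(6)
        )
        m = ch.b1.mean(axis=0)
        se = ch.b1.std(axis=0, ddof=1) / np.sqrt(200)  # generous ESS guess
        assert abs(m[0] - m[1]) < 4 * np.hypot(se[0], se[1])


class TestGewekeGettingItRight:
    def test_successive_conditional_simulation_preserves_prior(self):
        """Alternating Gibbs transitions with data re-simulation leaves the
        prior marginals of beta*, sigma_b^2 and r invariant (joint-
        distribution test of every conditional on a tiny model)."""
        I, J, n = 2, 3, 2
        rng = make_rng(2024)
        prior = PriorSpec(
            beta0=np.zeros(I),
            Sigma0=0.3 * np.eye(I),
            nu_b1=8.0, S_b1=0.4, nu_b2=8.0, S_b2=0.4,
            a0=8.0, b0=2.0,  # r prior mean 4, sd sqrt(8)/2
        )
        template = balanced_panel(I=I, J=J, K=1, n=n)
        design = build_design(template, include_blocks=False)
        covset = CovarianceSet.from_g1(np.eye(J), I)

        def draw_prior_state(sampler):
            st = sampler.init_state(rng)
            st.r = rng.gamma(prior.a0) / prior.b0
            st.sigma_b12 = prior.nu_b1 * prior.S_b1 / rng.chisquare(prior.nu_b1)
            st.sigma_b22 = prior.nu_b2 * prior.S_b2 / rng.chisquare(prior.nu_b2)
            st.beta_star = rng.multivariate_normal(np.zeros(I), 0.3 * np.eye(I))
            st.b1 = rng.normal(scale=np.sqrt(st.sigma_b12), size=J)
            st.b2 = rng.normal(scale=np.sqrt(st.sigma_b22), size=I * J)
            return st

        def simulate_given(st, sampler):
            eta_star = sampler.X @ st.beta_star + st.b1[sampler.line_idx]
            eta_star = eta_star + st.b2[sampler.cell_idx]
            pi = 1.0 / (1.0 + np.exp(-np.clip(eta_star, -30, 30)))
            return rng.negative_binomial(st.r, 1.0 - pi)

        sampler = BMNBSampler(template, design, covset, prior)
        st = draw_prior_state(sampler)
        cycles, keep_every = 6000, 2
        rs, s1s, betas = [], [], []
        for c in range(cycles):
            y = simulate_given(st, sampler)
            frame = template.frame.copy()
            frame["count"] = y
            panel = CountPanel.from_frame(frame)
            sampler2 = BMNBSampler(panel, design, covset, prior)
            sampler2.step(st, rng)
            if c % keep_every == 0:
                rs.append(st.r)
                s1s.append(st.sigma_b12)
                betas.append(st.beta_star[0])
        rs, s1s, betas = map(np.asarray, (rs, s1s, betas))

        def batch_se(x, nb=30):
            b = x[: len(x) // nb * nb].reshape(nb, -1).mean(axis=1)
            return b.std(ddof=1) / np.sqrt(nb)

        assert abs(rs.mean() - 4.0) < 5 * batch_se(rs)
        prior_s_mean = 8.0 * 0.4 / (8.0 - 2.0)
        assert abs(s1s.mean() - prior_s_mean) < 5 * batch_se(s1s)
        assert abs(betas.mean() - 0.0) < 5 * batch_se(betas)
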