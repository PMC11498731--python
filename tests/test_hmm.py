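"""Emission densities, forward/Viterbi against enumeration oracles, fitting."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats
from scipy.special import expit

from tigermove import hmm
from tigermove.hmm import EmissionParams, HmmFit


def random_instance(rng, T, p_cov=1):
    """Random 2-state parameter set + observation sequence (single burst)."""
    em = EmissionParams(
        mu=rng.uniform(50, 800, 2), sigma=rng.uniform(40, 900, 2),
        zeromass=rng.uniform(0.005, 0.1, 2),
        angle_mean=rng.uniform(-np.pi, np.pi, 2), rho=rng.uniform(0.05, 0.9, 2))
    beta = rng.normal(0, 1, size=(2, 1 + p_cov))
    s = rng.gamma(1.0, 300.0, T)
    s[rng.uniform(size=T) < 0.1] = 0.0
    ang = rng.uniform(-np.pi, np.pi, T)
    ang[0] = np.nan
    ang[rng.uniform(size=T) < 0.15] = np.nan
    Z = rng.normal(0, 1, size=(T, p_cov))
    return em, beta, s, ang, Z


def oracle_logdensities(s, ang, em):
    """Per-state emission log densities recomputed with scipy distributions."""
    T = len(s)
    logb = np.zeros((T, 2))
    for k in range(2):
        shape = em.mu[k] ** 2 / em.sigma[k] ** 2
        scale = em.sigma[k] ** 2 / em.mu[k]
        for t in range(T):
            if s[t] == 0:
                logb[t, k] = math.log(em.zeromass[k])
            else:
                logb[t, k] = (math.log1p(-em.zeromass[k])
                              + stats.gamma.logpdf(s[t], shape, scale=scale))
            if np.isfinite(ang[t]):
                # scipy wrapcauchy lives on [0, 2pi); shift by the mean direction
                x = (ang[t] - em.angle_mean[k]) % (2 * np.pi)
                logb[t, k] += stats.wrapcauchy.logpdf(x, em.rho[k])
    return logb


def oracle_transition(z, beta):
    g01 = expit(beta[0, 0] + beta[0, 1:] @ z)
    g10 = expit(beta[1, 0] + beta[1, 1:] @ z)
    return np.array([[1 - g01, g01], [g10, 1 - g10]])


def oracle_forward_and_viterbi(s, ang, Z, em, beta):
    """Brute force over all 2^T state sequences."""
    T = len(s)
    logb = oracle_logdensities(s, ang, em)
    gammas = [oracle_transition(Z[t], beta) for t in range(T)]
    G0 = gammas[0]
    delta0 = np.array([G0[1, 0], G0[0, 1]]) / (G0[0, 1] + G0[1, 0])
    best_lp, best_path = -np.inf, None
    total = -np.inf
    for seq in itertools.product((0, 1), repeat=T):
        lp = math.log(delta0[seq[0]]) + logb[0, seq[0]]
        for t in range(1, T):
            lp += math.log(gammas[t][seq[t - 1], seq[t]]) + logb[t, seq[t]]
        total = np.logaddexp(total, lp)
        if lp > best_lp:
            best_lp, best_path = lp, seq
    return total, np.array(best_path)


def package_arrays(s, ang, Z):
    starts = np.array([0, len(s)], dtype=np.int64)
    return s, ang, Z, starts


class TestStepDensity:
    def test_zero_inflation_off_reduces_to_gamma(self, rng):
        s = rng.gamma(2.0, 100.0, 50)
        got = hmm.step_logdensity(s, 300.0, 150.0, 0.0)
        want = stats.gamma.logpdf(s, 4.0, scale=75.0)  # shape mu^2/sd^2, scale sd^2/mu
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_zero_step_hits_the_point_mass(self):
        assert hmm.step_logdensity(np.array([0.0]), 100.0, 50.0, 0.01)[0] == \
            pytest.approx(math.log(0.01))

    def test_density_normalizes_by_quadrature(self):
        mu, sd, z0 = 100.0, 50.0, 0.01
        dens = lambda s: math.exp(hmm.step_logdensity(np.array([s]), mu, sd, z0)[0])
        integral, _ = integrate.quad(dens, 1e-12, np.inf)
        assert integral + z0 == pytest.approx(1.0, abs=1e-6)

    def test_negative_step_rejected(self):
        with pytest.raises(hmm.HmmError):
            hmm.step_logdensity(np.array([-1.0]), 100.0, 50.0)


class TestAngleDensity:
    def test_zero_concentration_is_circular_uniform(self, rng):
        th = rng.uniform(-np.pi, np.pi, 20)
        np.testing.assert_allclose(hmm.angle_logdensity(th, 0.3, 0.0),
                                   math.log(1 / (2 * math.pi)), atol=1e-12)

    def test_symmetry_about_the_mean_direction(self):
        for d in (0.1, 0.7, 2.0):
            assert hmm.angle_logdensity(np.array([0.5 + d]), 0.5, 0.6)[0] == \
                pytest.approx(hmm.angle_logdensity(np.array([0.5 - d]), 0.5, 0.6)[0])

    def test_normalizes_by_quadrature(self):
        f = lambda th: math.exp(hmm.angle_logdensity(np.array([th]), 0.4, 0.7)[0])
        integral, _ = integrate.quad(f, -np.pi, np.pi, limit=200)
        assert integral == pytest.approx(1.0, abs=1e-8)

    def test_matches_scipy_wrapped_cauchy(self, rng):
        th = rng.uniform(-np.pi, np.pi, 30)
        rho = 0.55
        got = hmm.angle_logdensity(th, 0.0, rho)
        want = stats.wrapcauchy.logpdf(th % (2 * np.pi), rho)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_invalid_concentration_rejected(self):
        with pytest.raises(hmm.HmmError):
            hmm.angle_logdensity(np.array([0.0]), 0.0, 1.0)


class TestTransitionMatrix:
    def test_zero_coefficients_give_half_everywhere(self):
        G = hmm.transition_matrix(np.zeros(3), np.zeros((2, 4)))
        np.testing.assert_allclose(G, 0.5)

    def test_rows_sum_to_one_for_random_coefficients(self, rng):
        for _ in range(10):
            G = hmm.transition_matrix(rng.normal(size=2), rng.normal(size=(2, 3)))
            np.testing.assert_allclose(G.sum(axis=1), 1.0, atol=1e-14)
            assert np.all((G > 0) & (G < 1))

    def test_saturated_intercepts_give_near_identity(self):
        beta = np.array([[-10.0, 0.0], [-10.0, 0.0]])
        G = hmm.transition_matrix(np.zeros(1), beta)
        np.testing.assert_allclose(np.diag(G), 1.0, atol=1e-4)


class TestForward:
    def test_single_step_is_initial_weighted_emission_mixture(self, rng):
        em, beta, s, ang, Z = random_instance(rng, 1)
        got = hmm.forward_loglik(*package_arrays(s, ang, Z), em, beta)
        want, _ = oracle_forward_and_viterbi(s, ang, Z, em, beta)
        assert got == pytest.approx(want, abs=1e-10)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_enumeration_over_all_state_sequences(self, seed):
        rng = np.random.default_rng(seed)
        T = int(rng.integers(2, 9))
        em, beta, s, ang, Z = random_instance(rng, T)
        got = hmm.forward_loglik(*package_arrays(s, ang, Z), em, beta)
        want, _ = oracle_forward_and_viterbi(s, ang, Z, em, beta)
        assert got == pytest.approx(want, abs=1e-8)

    def test_invariant_under_state_relabeling(self, rng):
        em, beta, s, ang, Z = random_instance(rng, 6)
        ll = hmm.forward_loglik(*package_arrays(s, ang, Z), em, beta)
        em2 = EmissionParams(mu=em.mu[::-1], sigma=em.sigma[::-1],
                             zeromass=em.zeromass[::-1],
                             angle_mean=em.angle_mean[::-1], rho=em.rho[::-1])
        beta2 = beta[::-1]
        ll2 = hmm.forward_loglik(*package_arrays(s, ang, Z), em2, beta2)
        assert ll == pytest.approx(ll2, abs=1e-10)


class TestViterbi:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_argmax(self, seed):
        rng = np.random.default_rng(seed + 100)
        T = int(rng.integers(2, 13))
        em, beta, s, ang, Z = random_instance(rng, T)
        _, want = oracle_forward_and_viterbi(s, ang, Z, em, beta)
        fit = HmmFit(emissions=em, trans_beta=beta, covariates=("z",),
                     standardizer=None, loglik=0.0, theta=np.zeros(1), cov=None,
                     n_steps=T, n_starts=1, converged=True)
        steps = pd.DataFrame({"animal": "a", "burst": 0, "step": s, "angle": ang,
                              "z": Z[:, 0]})
        got = hmm.viterbi(steps, fit)
        np.testing.assert_array_equal(got, want)

    def test_decoding_accuracy_on_separated_states(self, hmm_steps):
        """Strongly separated emissions: decoded states match truth > 90%."""
        fit = hmm.fit_hmm(hmm_steps, covariates=("dist_village",), n_starts=2,
                          seed=1, compute_cov=False)
        decoded = hmm.viterbi(hmm_steps, fit)
        acc = (decoded == hmm_steps.attrs["states"]).mean()
        assert acc > 0.9


class TestFit:
    def test_recovers_generating_emission_means(self, hmm_steps, land_std):
        fit = hmm.fit_hmm(hmm_steps, covariates=("dist_village", "dist_water", "ndvi"),
                          standardizer=land_std, n_starts=2, seed=0,
                          compute_cov=False)
        assert fit.emissions.mu[0] == pytest.approx(100.0, rel=0.10)
        assert fit.emissions.mu[1] == pytest.approx(700.0, rel=0.10)
        assert fit.emissions.mu[0] < fit.emissions.mu[1]  # label order normalized

    def test_fitted_loglik_not_below_initial_loglik(self, hmm_steps):
        fit = hmm.fit_hmm(hmm_steps, covariates=("dist_village",), n_starts=1,
                          seed=0, compute_cov=False)
        s, ang, Z, starts, std = hmm._step_arrays(hmm_steps, ("dist_village",), None)
        em0 = EmissionParams(mu=[100, 700], sigma=[50, 1000],
                             zeromass=[1e-4, 0.05], angle_mean=[0, 0],
                             rho=[0.3, 0.7])
        beta0 = np.zeros((2, 2))
        beta0[:, 0] = -2.0
        ll0 = hmm.forward_loglik(s, ang, Z, starts, em0, beta0)
        assert fit.loglik >= ll0 - 1e-9

    def test_refit_from_perturbed_start_reaches_same_optimum(self, hmm_steps):
        base = hmm.fit_hmm(hmm_steps, covariates=("dist_village",), n_starts=3,
                           seed=0, compute_cov=False)
        perturbed = ((150.0, 75.0, 0.015, 0.45), (350.0, 500.0, 0.025, 0.35))
        refit = hmm.fit_hmm(hmm_steps, covariates=("dist_village",),
                            initial_emissions=perturbed, n_starts=3, seed=5,
                            compute_cov=False)
        assert refit.loglik == pytest.approx(base.loglik, abs=1e-4)


class TestStateBudget:
    def test_all_travelling(self):
        np.testing.assert_allclose(hmm.state_budget([1, 1, 1]), [0.0, 1.0])

    def test_counting(self):
        np.testing.assert_allclose(hmm.state_budget([0, 1, 1, 1]), [0.25, 0.75])

    def test_proportions_sum_to_one(self, rng):
        for _ in range(5):
            b = hmm.state_budget(rng.integers(0, 2, 30))
            assert b.sum() == pytest.approx(1.0)


class TestStationary:
    def test_symmetric_chain_is_half_half(self):
        np.testing.assert_allclose(hmm.stationary_distribution(0.3, 0.3), [0.5, 0.5])

    @pytest.mark.parametrize("seed", [0])
    def test_matches_left_eigenvector_on_random_matrices(self, seed):
        """Closed form delta_0 = g10/(g01+g10) vs the leading left eigenvector."""
        rng = np.random.default_rng(seed)
        for _ in range(100):
            g01, g10 = rng.uniform(0.01, 0.99, 2)
            d = hmm.stationary_distribution(g01, g10)
            G = np.array([[1 - g01, g01], [g10, 1 - g10]])
            w, v = np.linalg.eig(G.T)
            lead = np.real(v[:, np.argmax(np.real(w))])
            lead /= lead.sum()
            np.testing.assert_allclose(d, lead, atol=1e-12)

    def test_curve_probabilities_sum_to_one_and_monotone_when_only_into_travel(self):
        # positive slope only on the encamp->travel transition: travelling
        # probability must rise monotonically along the covariate grid
        em = EmissionParams(mu=[100, 700], sigma=[50, 1000], zeromass=[0.01, 0.05],
                            angle_mean=[0, 0], rho=[0.3, 0.7])
        beta = np.array([[-1.0, 0.8], [-1.5, 0.0]])
        fit = HmmFit(emissions=em, trans_beta=beta, covariates=("dist_village",),
                     standardizer=None, loglik=0.0, theta=np.zeros(14), cov=None,
                     n_steps=10, n_starts=1, converged=True)
        curve = hmm.stationary_curve(fit, "dist_village", np.linspace(-2, 2, 15))
        np.testing.assert_allclose(curve["p_encamping"] + curve["p_travelling"],
                                   1.0, atol=1e-12)
        assert np.all(np.diff(curve["p_travelling"]) > 0)

    def test_unknown_covariate_rejected(self, rng):
        em = EmissionParams(mu=[1, 2], sigma=[1, 1], zeromass=[0, 0],
                            angle_mean=[0, 0], rho=[0, 0])
        fit = HmmFit(emissions=em, trans_beta=np.zeros((2, 2)),
                     covariates=("ndvi",), standardizer=None, loglik=0.0,
                     theta=np.zeros(14), cov=None, n_steps=1, n_starts=1,
                     converged=True)
        with pytest.raises(hmm.HmmError):
            hmm.stationary_curve(fit, "elevation", [0.0])
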