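"""Sampler correctness: determinism, Gibbs conditionals, enumeration oracle."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from lionscr.mcmc import ChainConfig, Sampler, inclusion_probability, run
from lionscr.model import (LatentState, ModelSpec, Parameters,
                           complete_data_loglik)


class TestInclusionProbability:
    def test_no_information_returns_psi(self):
        assert inclusion_probability(0.47, 1.0) == pytest.approx(0.47)

    def test_certain_detection_limit(self):
        assert inclusion_probability(0.47, 0.0) == 0.0

    def test_posterior_mean_plugin(self):
        # psi * p0 / (psi * p0 + 1 - psi) with psi = 0.47, p0 = 0.5
        assert inclusion_probability(0.47, 0.5) == pytest.approx(0.235 / 0.765)
        assert inclusion_probability(0.47, 0.5) == pytest.approx(0.307, abs=5e-4)


class TestDeterminism:
    def test_identical_seed_identical_output(self, tiny_instance):
        ss, traps, effort, data, spec, params = tiny_instance
        cc = ChainConfig(seed=11, n_chains=2, n_iter=300, burn_in=50,
                         latent_stride=3)
        a = run(spec, data, ss, cc)
        b = run(spec, data, ss, cc)
        for name in a.names:
            assert np.array_equal(a.draws[name], b.draws[name])
        assert np.array_equal(a.n_super, b.n_super)
        assert np.array_equal(a.latent_s, b.latent_s)
        assert np.array_equal(a.loglik, b.loglik)

    def test_chains_differ_from_each_other(self, tiny_instance):
        ss, traps, effort, data, spec, params = tiny_instance
        cc = ChainConfig(seed=11, n_chains=2, n_iter=300, burn_in=50)
        s = run(spec, data, ss, cc)
        assert not np.array_equal(s.draws["lambda0"][0], s.draws["lambda0"][1])


class TestInvariants:
    def test_n_super_never_below_observed(self, small_fit, small_bundle):
        assert small_fit.n_super.min() >= small_bundle.capture.n_observed

    def test_acceptance_rates_are_probabilities(self, small_fit):
        for name, rates in small_fit.acceptance.items():
            assert np.all(rates >= 0) and np.all(rates <= 1), name

    def test_stored_loglik_matches_reference(self, tiny_instance):
        """The sampler's incremental log-likelihood equals the reference
        complete-data computation at every stored latent snapshot."""
        ss, traps, effort, data, spec, params = tiny_instance
        cc = ChainConfig(seed=21, n_chains=1, n_iter=200, burn_in=20,
                         latent_stride=1)
        s = run(spec, data, ss, cc)
        for l in range(0, s.latent_iters.size, 17):
            it = int(s.latent_iters[l])
            p = s.parameters_at(0, it)
            lat = LatentState(z=s.latent_z[0, l], s=s.latent_s[0, l],
                              sex=s.latent_sex[0, l])
            ref = complete_data_loglik(p, lat, data, spec, ss)
            assert s.loglik[0, it] == pytest.approx(ref, rel=1e-9)

    def test_psi_gibbs_matches_beta_conjugacy(self, tiny_instance):
        """With a Uniform prior the psi draw given z is Beta(1+sum z,
        1+M-sum z); check the long-run moments against the closed form."""
        ss, traps, effort, data, spec, params = tiny_instance
        sampler = Sampler(spec, data, ss, ChainConfig(seed=0, n_iter=10, burn_in=1))
        rng = np.random.default_rng(123)
        sampler.init_state(rng)
        sampler.z = np.array([1, 1, 0], dtype=np.int8)
        draws = []
        for _ in range(4000):
            sampler.update_parameters(rng)
            draws.append(sampler.params.psi)
            sampler.z = np.array([1, 1, 0], dtype=np.int8)
        a, b = 1 + 2, 1 + 1
        target = stats.beta(a, b)
        draws = np.array(draws)
        assert draws.mean() == pytest.approx(target.mean(), abs=0.01)
        assert draws.std() == pytest.approx(target.std(), abs=0.01)


def enumerate_posterior(ss, data, spec, params):
    """Brute-force posterior over (z, s, sex) for the tiny instance.

    Excluded individuals carry no (s, sex) mass in the complete-data
    likelihood, so the uniform prior mass is restored when enumerating
    their states to avoid overcounting.
    """
    nh = ss.n_habitat
    M = spec.M
    pN = np.zeros(M + 1)
    ps = np.zeros(nh)
    for z_aug in itertools.product([0, 1], repeat=M - 1):
        z = np.array([1, *z_aug])
        for s in itertools.product(range(nh), repeat=M):
            for sex in itertools.product([0, 1], repeat=M):
                lat = LatentState(z=z, s=np.array(s), sex=np.array(sex))
                lw = complete_data_loglik(params, lat, data, spec, ss)
                lw += sum(math.log(1.0 / (2 * nh))
                          for i in range(M) if z[i] == 0)
                w = math.exp(lw)
                pN[z.sum()] += w
                ps[s[0]] += w
    total = pN.sum()
    return pN / total, ps / total


def chain_level_bound(per_chain, floor):
    """3x the chain-level standard error, floored.

    Independent chains give unbiased SE estimates, but with few chains the
    estimate itself is noisy (chi-squared with n_chains - 1 df), so a small
    absolute floor guards against chance underestimation.
    """
    se = per_chain.std(ddof=1) / math.sqrt(per_chain.size)
    return max(3 * se, floor)


@pytest.fixture(scope="module")
def oracle(tiny_instance):
    ss, traps, effort, data, spec, params = tiny_instance
    return enumerate_posterior(ss, data, spec, params)


class TestEnumerationOracle:
    """Latent-state sampler vs exhaustive enumeration (fixed parameters)."""

    def test_n_super_distribution(self, oracle, oracle_posterior):
        pN, _ = oracle
        N = oracle_posterior.n_super
        for k in range(4):
            per_chain = (N == k).mean(axis=1)
            err = abs(per_chain.mean() - pN[k])
            assert err <= chain_level_bound(per_chain, 0.015), k

    def test_activity_center_distribution(self, oracle, oracle_posterior):
        _, ps = oracle
        s_obs = oracle_posterior.latent_s[:, :, 0]
        for p in range(3):
            per_chain = (s_obs == p).mean(axis=1)
            err = abs(per_chain.mean() - ps[p])
            assert err <= chain_level_bound(per_chain, 0.015), p

    def test_n_super_mean(self, oracle, oracle_posterior):
        pN, _ = oracle
        target = np.dot(np.arange(4), pN)
        per_chain = oracle_posterior.n_super.mean(axis=1)
        err = abs(per_chain.mean() - target)
        assert err <= chain_level_bound(per_chain, 0.03)
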