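"""Bayesian decoding: closed forms, sampler invariance, enumeration oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare, poisson

import popglm as pg
from popglm.data import CovariateTable
from popglm.decode import (
    CoupledDecoder,
    DecoderConfig,
    TuningCurveDecoder,
    _gibbs_chain,
    decoding_accuracy,
    ordered_overrelaxation_update,
)
from popglm.glm import ModelFit

from _oracles import gibbs_sweep_stationary, symmetric_joint_pmf

BS = pg.BasisSpec("cosine_direction")


def _stim_table(directions=(0.0, 90.0)):
    return CovariateTable(pd.DataFrame({"direction": np.asarray(directions)}))


def _fits(mu, alpha, beta):
    """Full-model fits for a small network with coupling matrix beta."""
    n = len(mu)
    beta = np.asarray(beta, dtype=float)
    fits = []
    for i in range(n):
        src = np.array([j for j in range(n) if j != i])
        fits.append(
            ModelFit("full", mu[i], np.asarray(alpha[i], dtype=float),
                     beta[i, src], src, 0.0, 0.0, neuron=i, basis_spec=BS)
        )
    return fits


def _tc_fits(mu, alpha):
    return [
        ModelFit("tuning", mu[i], np.asarray(alpha[i], dtype=float), None,
                 None, 0.0, 0.0, neuron=i, basis_spec=BS)
        for i in range(len(mu))
    ]


class TestDecodeTC:
    def test_identical_rates_give_uniform_posterior(self):
        fits = _tc_fits([np.log(2.0)], [[0.0, 0.0]])
        post = pg.decode_tc(np.array([[3]]), fits, _stim_table())
        np.testing.assert_allclose(post.probabilities[0], [0.5, 0.5])

    def test_closed_form_two_stimuli(self):
        # rates 1 and 3, observed 0: posterior ∝ (e^-1, e^-3)
        fits = _tc_fits([0.0], [[np.log(3.0) / 1.0 * 0.5, 0.0]])
        # construct rates directly: lambda(s1)=1 at 90 deg (cos=0), and use
        # alpha so that lambda at 0 deg is 3: exp(0 + a) = 3
        fits = [ModelFit("tuning", 0.0, np.array([np.log(3.0), 0.0]), None,
                         None, 0.0, 0.0, neuron=0, basis_spec=BS)]
        post = pg.decode_tc(np.array([[0]]), fits, _stim_table((90.0, 0.0)))
        expect = np.array([np.exp(-1.0), np.exp(-3.0)])
        expect /= expect.sum()
        np.testing.assert_allclose(post.probabilities[0], expect, atol=1e-12)
        assert post.probabilities[0][0] == pytest.approx(0.8808, abs=1e-4)

    def test_posterior_rows_normalized(self, cosine_population, cosine_basis):
        _, counts, cov = cosine_population
        tc = pg.fit_population(counts, cov, cosine_basis, "tuning", penalty=0.0)
        post = pg.decode_tc(counts, tc, _stim_table(np.arange(8) * 45.0))
        np.testing.assert_allclose(post.probabilities.sum(axis=1), 1.0)

    def test_accuracy_above_chance_and_grows_with_population(self):
        spec = pg.PopulationSpec(
            n_neurons=12, n_trials=800, tuning_kind="cosine", seed=61,
            rate_range=(3.0, 12.0),
        )
        counts, cov = pg.simulate_tuned_population(spec)
        bs = pg.BasisSpec("cosine_direction")
        stim = _stim_table(np.arange(8) * 45.0)
        labels = cov["direction"]
        accs = []
        for size in (2, 12):
            subset = np.arange(size)
            tc = pg.fit_population(counts, cov, bs, "tuning",
                                   subset=subset, penalty=0.0)
            post = pg.decode_tc(
                counts.counts[:, subset], tc, stim,
                stimuli=np.arange(8) * 45.0,
            )
            accs.append(decoding_accuracy(post, labels))
        assert accs[-1] > 1 / 8 + 0.1
        assert accs[-1] > accs[0]


class TestOrderedOverrelaxation:
    def test_rate_must_be_positive(self):
        with pytest.raises(ValueError):
            ordered_overrelaxation_update(1, 0.0, 5, seed=1)

    def test_marginal_invariance_chisquare(self):
        # iterating the update from Poisson starts stays Poisson(rate)
        rate, n = 3.0, 50000
        rng = np.random.default_rng(71)
        np.random.seed(72)
        x = rng.poisson(rate, size=n)
        for _ in range(2):
            x = np.array([
                ordered_overrelaxation_update(int(v), rate, 7) for v in x
            ])
        kmax = 12
        obs = np.bincount(np.minimum(x, kmax), minlength=kmax + 1)
        probs = poisson.pmf(np.arange(kmax), rate)
        probs = np.append(probs, 1 - probs.sum())
        stat, p = chisquare(obs, probs * n)
        assert p > 0.01

    def test_k1_returns_fresh_draw_distribution(self):
        rate, n = 2.0, 50000
        np.random.seed(73)
        rng = np.random.default_rng(74)
        start = rng.poisson(rate, size=n)
        out = np.array([
            ordered_overrelaxation_update(int(v), rate, 1) for v in start
        ])
        kmax = 10
        obs = np.bincount(np.minimum(out, kmax), minlength=kmax + 1)
        probs = poisson.pmf(np.arange(kmax), rate)
        probs = np.append(probs, 1 - probs.sum())
        stat, p = chisquare(obs, probs * n)
        assert p > 0.01

    def test_negative_serial_dependence_vs_plain_gibbs(self):
        # single neuron, no coupling: chain of marginal updates
        mu = [np.log(4.0)]
        alpha = [[0.0, 0.0]]
        beta = np.zeros((1, 1))
        eta = np.array([mu[0]])
        n_samp = 20000
        over, _ = _gibbs_chain(eta, beta, n_samp, 100, 15, -1, 81)
        plain, _ = _gibbs_chain(eta, beta, n_samp, 100, 1, -1, 82)

        def lag1(x):
            x = x[:, 0].astype(float)
            return np.corrcoef(x[:-1], x[1:])[0, 1]

        assert lag1(over) < lag1(plain) + 0.01
        assert lag1(over) < 0.0  # over-relaxation anti-correlates the chain


class TestGibbsSampler:
    def test_independent_network_marginal_means(self):
        mu = [np.log(2.0), np.log(5.0), np.log(1.0)]
        alpha = [[0.3, 0], [0, -0.2], [0.1, 0.1]]
        fits = _fits(mu, alpha, np.zeros((3, 3)))
        cfg = DecoderConfig(n_samples=4000, burn_in=200, seed=91)
        samples = pg.gibbs_sample_joint(fits, _stim_table(), cfg)
        F = pg.build_basis(_stim_table(), BS)
        expect = np.exp([mu[i] + F[0] @ np.asarray(alpha[i]) for i in range(3)])
        got = samples.mean(axis=0)
        mcse = samples.std(axis=0) / np.sqrt(len(samples))
        assert np.all(np.abs(got - expect) < 4 * mcse + 1e-9)

    def test_positive_coupling_positive_correlation(self):
        beta = np.array([[0.0, 0.1], [0.1, 0.0]])
        fits = _fits([np.log(2.0), np.log(2.0)], [[0, 0], [0, 0]], beta)
        cfg = DecoderConfig(n_samples=5000, burn_in=500, seed=92, max_count=30)
        samples = pg.gibbs_sample_joint(fits, _stim_table(), cfg)
        r = np.corrcoef(samples, rowvar=False)[0, 1]
        assert r > 0.05

    def test_joint_pmf_matches_enumeration_oracle(self):
        # symmetric coupling: the truncated joint is an exact Gibbs measure
        mu = [np.log(2.0), np.log(3.0), np.log(1.5)]
        alpha = [[0.4, 0], [0, 0.3], [0.2, 0.2]]
        beta = np.array(
            [[0.0, 0.06, -0.04], [0.06, 0.0, 0.03], [-0.04, 0.03, 0.0]]
        )
        MAXC = 15
        fits = _fits(mu, alpha, beta)
        cfg = DecoderConfig(n_samples=30000, burn_in=500, seed=93, max_count=MAXC)
        samples = pg.gibbs_sample_joint(fits, _stim_table(), cfg)
        F = pg.build_basis(_stim_table(), BS)
        eta = np.array([mu[i] + F[0] @ np.asarray(alpha[i]) for i in range(3)])
        oracle = symmetric_joint_pmf(eta, beta, MAXC)
        emp = np.zeros_like(oracle)
        for a, b, c in samples:
            emp[a, b, c] += 1
        emp /= emp.sum()
        assert 0.5 * np.abs(emp - oracle).sum() < 0.05

    def test_power_iteration_agrees_with_gibbs_measure(self):
        # secondary oracle: stationary law of the sweep kernel
        mu = [np.log(1.5), np.log(2.0)]
        beta = np.array([[0.0, 0.08], [0.08, 0.0]])
        eta = np.array(mu)
        states, p = gibbs_sweep_stationary(eta, beta, max_count=12, n_iter=500)
        oracle = symmetric_joint_pmf(eta, beta, 12)
        p_grid = np.zeros_like(oracle)
        for s, pv in zip(states, p):
            p_grid[tuple(s)] = pv
        assert 0.5 * np.abs(p_grid - oracle).sum() < 1e-6


class TestChainRule:
    def test_beta_zero_equals_independent_product(self):
        mu = [np.log(2.0), np.log(3.0)]
        alpha = [[0.5, 0], [0, 0.5]]
        fits = _fits(mu, alpha, np.zeros((2, 2)))
        cfg = DecoderConfig(n_samples=2000, burn_in=100, seed=94)
        samples = pg.gibbs_sample_joint(fits, _stim_table(), cfg)
        obs = np.array([1, 4])
        est = pg.chain_rule_joint_probability(obs, fits, _stim_table(), samples)
        F = pg.build_basis(_stim_table(), BS)
        rates = np.exp([mu[i] + F[0] @ np.asarray(alpha[i]) for i in range(2)])
        exact = poisson.logpmf(obs, rates).sum()
        assert abs(est - exact) < 1e-9  # conditionals are sample-independent

    def test_matches_enumeration_within_tenth_nat(self):
        mu = [np.log(2.0), np.log(3.0)]
        alpha = [[0.4, 0], [0, 0.3]]
        beta = np.array([[0.0, 0.07], [0.07, 0.0]])
        MAXC = 30
        fits = _fits(mu, alpha, beta)
        cfg = DecoderConfig(n_samples=5000, burn_in=500, seed=95, max_count=MAXC)
        samples = pg.gibbs_sample_joint(fits, _stim_table(), cfg)
        F = pg.build_basis(_stim_table(), BS)
        eta = np.array([mu[i] + F[0] @ np.asarray(alpha[i]) for i in range(2)])
        oracle = symmetric_joint_pmf(eta, beta, MAXC)
        for obs in ([2, 3], [0, 1], [4, 6]):
            est = pg.chain_rule_joint_probability(
                np.array(obs), fits, _stim_table(), samples, max_count=MAXC
            )
            exact = np.log(oracle[tuple(obs)])
            assert abs(est - exact) < 0.1

    def test_mc_error_shrinks_with_sample_size(self):
        mu = [np.log(2.0), np.log(2.5)]
        beta = np.array([[0.0, 0.08], [0.08, 0.0]])
        fits = _fits(mu, [[0.3, 0], [0, 0.3]], beta)
        obs = np.array([3, 2])
        stds = []
        for n_samples in (400, 1600):
            vals = []
            for seed in range(16):
                cfg = DecoderConfig(
                    n_samples=n_samples, burn_in=200, seed=200 + seed,
                    max_count=30,
                )
                samples = pg.gibbs_sample_joint(fits, _stim_table(), cfg)
                vals.append(
                    pg.chain_rule_joint_probability(
                        obs, fits, _stim_table(), samples, max_count=30
                    )
                )
            stds.append(np.std(vals))
        ratio = stds[0] / stds[1]
        # quadrupling the samples should halve the MC standard deviation;
        # the band is wide because the std estimates use only 16 chains
        assert 1.3 < ratio < 2.8


class TestDecodeFull:
    def test_reduces_to_tc_when_uncoupled(self):
        mu = [np.log(2.0), np.log(3.0), np.log(1.0)]
        alpha = [[0.6, 0], [0, 0.6], [-0.4, 0.2]]
        full = _fits(mu, alpha, np.zeros((3, 3)))
        tc = _tc_fits(mu, alpha)
        stim = _stim_table(np.arange(4) * 90.0)
        rng = np.random.default_rng(96)
        Y = rng.poisson(2.0, size=(20, 3))
        cfg = DecoderConfig(n_samples=1000, burn_in=100, seed=97)
        p_full = pg.decode_full(Y, full, stim, cfg).probabilities
        p_tc = pg.decode_tc(Y, tc, stim).probabilities
        assert np.max(np.abs(p_full - p_tc)) < 0.02

    def test_accuracy_invariant_to_stimulus_relabeling(self):
        spec = pg.PopulationSpec(
            n_neurons=6, n_trials=400, tuning_kind="cosine", seed=98,
        )
        counts, cov = pg.simulate_tuned_population(spec)
        tc = pg.fit_population(counts, cov, BS, "tuning", penalty=0.0)
        stim = _stim_table(np.arange(8) * 45.0)
        labels = cov["direction"]
        post = pg.decode_tc(counts, tc, stim, stimuli=np.arange(8) * 45.0)
        acc = decoding_accuracy(post, labels)
        # relabel: permute stimulus identities consistently
        perm = np.roll(np.arange(8), 3)
        post2 = pg.PosteriorOverStimuli(
            post.stimuli[perm], post.log_likelihood[:, perm]
        )
        # decoded identities unchanged as labels follow the permutation
        acc2 = decoding_accuracy(post2, labels)
        assert acc == pytest.approx(acc2)

    def test_bit_identical_given_seed(self):
        mu = [np.log(2.0), np.log(2.5)]
        beta = np.array([[0.0, 0.08], [0.08, 0.0]])
        fits = _fits(mu, [[0.4, 0], [0, 0.4]], beta)
        stim = _stim_table((0.0, 90.0, 180.0))
        Y = np.array([[2, 3], [0, 1]])
        cfg = DecoderConfig(n_samples=500, burn_in=100, seed=314)
        p1 = pg.decode_full(Y, fits, stim, cfg).probabilities
        p2 = pg.decode_full(Y, fits, stim, cfg).probabilities
        np.testing.assert_array_equal(p1, p2)

    def test_full_model_helps_with_noise_correlations(self):
        # populations with common input: coupled decoder >= independent one
        wins = 0
        n_sets = 6
        for k in range(n_sets):
            spec = pg.PopulationSpec(
                n_neurons=8, n_trials=700, tuning_kind="cosine",
                common_input_rho=0.45, common_input_gain=0.8,
                rate_range=(2.0, 8.0), seed=500 + k,
            )
            counts, cov = pg.simulate_tuned_population(spec)
            stim = _stim_table(np.arange(8) * 45.0)
            labels = cov["direction"]
            tc = pg.fit_population(counts, cov, BS, "tuning", penalty=0.0)
            full = pg.fit_population(counts, cov, BS, "full", seed=k,
                                     penalty="cv")
            p_tc = pg.decode_tc(counts, tc, stim, stimuli=np.arange(8) * 45.0)
            cfg = DecoderConfig(n_samples=1500, burn_in=300, seed=600 + k)
            p_full = pg.decode_full(counts, full, stim, cfg,
                                    stimuli=np.arange(8) * 45.0)
            a_tc = decoding_accuracy(p_tc, labels)
            a_full = decoding_accuracy(p_full, labels)
            if a_full >= a_tc:
                wins += 1
        assert wins >= n_sets / 2
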