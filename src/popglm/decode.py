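"""Bayesian decoding of discrete stimuli from population spike counts.

Under the tuning-only model the neurons are conditionally independent
given the stimulus, so the likelihood of a trial's count vector factorises
into per-neuron Poisson terms and the posterior over the (uniform-prior)
stimulus set is available in closed form.

Under the full model the coupling is instantaneous, the joint has no
product form, and the likelihood P(y | s) must be approximated.  We draw
samples from the joint via Gibbs sampling over the model's conditionals —
using ordered over-relaxation (draw several values from the conditional,
sort them together with the current value, and return the mirrored order
statistic) to induce negative serial dependence and speed mixing — and
then estimate the joint probability of an observed count vector with a
chain-rule estimator: each factor P(y_i | y_{<i}, s) is a Monte-Carlo
expectation, over the Gibbs samples, of the analytic conditional Poisson
likelihood with the not-yet-fixed neurons filled in from the sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.special import gammaln, logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin

from .basis import build_basis
from .data import CovariateTable, SpikeCounts
from .glm import MAX_LINPRED, ModelFit

__all__ = [
    "DecoderConfig",
    "PosteriorOverStimuli",
    "ordered_overrelaxation_update",
    "gibbs_sample_joint",
    "chain_rule_joint_probability",
    "decode_tc",
    "decode_full",
    "TuningCurveDecoder",
    "CoupledDecoder",
    "decoding_accuracy",
]


@dataclass
class DecoderConfig:
    """Gibbs-sampler settings for the full-model decoder.

    ``n_samples`` retained sweeps after ``burn_in`` discarded sweeps;
    ``overrelax_order`` is the number of conditional draws per ordered
    over-relaxed update.  ``max_count`` truncates the count space (used by
    the small-network enumeration cross-checks); None leaves it unbounded.
    """

    n_samples: int = 5000
    burn_in: int = 500
    overrelax_order: int = 15
    seed: int = 0
    max_count: int | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.burn_in < 1 or self.overrelax_order < 1:
            raise ValueError("n_samples, burn_in, overrelax_order must be >= 1")


@dataclass
class PosteriorOverStimuli:
    """Per-trial posterior over a discrete stimulus set (uniform prior)."""

    stimuli: np.ndarray  # stimulus identifiers, length S
    log_likelihood: np.ndarray  # (n_trials, S) log P(y | s)
    probabilities: np.ndarray = field(init=False)  # (n_trials, S), rows sum to 1
    decoded: np.ndarray = field(init=False)  # argmax stimulus index per trial

    def __post_init__(self) -> None:
        ll = np.asarray(self.log_likelihood, dtype=float)
        self.probabilities = np.exp(ll - logsumexp(ll, axis=1, keepdims=True))
        self.decoded = np.argmax(self.probabilities, axis=1)


# ---------------------------------------------------------------------------
# Numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _draw_count(rate, max_count):
    """One draw from Poisson(rate), truncated to [0, max_count] if set."""
    if max_count < 0:
        return np.random.poisson(rate)
    # inverse CDF over the renormalized truncated support
    p = np.exp(-rate)
    z = p
    for k in range(1, max_count + 1):
        p *= rate / k
        z += p
    u = np.random.random() * z
    p = np.exp(-rate)
    c = p
    k = 0
    while k < max_count:
        if u <= c:
            break
        k += 1
        p *= rate / k
        c += p
    return k


@njit(cache=True)
def _oor_update(current, rate, k_or, max_count):
    """Ordered over-relaxation: mirrored order statistic around the current
    value, ties among equal counts broken uniformly at random."""
    pool = np.empty(k_or + 1, dtype=np.int64)
    for m in range(k_or):
        pool[m] = _draw_count(rate, max_count)
    pool[k_or] = current
    pool.sort()
    lo = np.searchsorted(pool, current, side="left")
    hi = np.searchsorted(pool, current, side="right")
    k = lo + int(np.random.random() * (hi - lo))
    return pool[k_or - k]


@njit(cache=True)
def _gibbs_chain(eta_stim, beta, n_samples, burn_in, k_or, max_count, seed):
    """Sample population count vectors from the coupled joint.

    One retained sample per sweep; each sweep updates every neuron once,
    in a freshly randomized order, from its conditional Poisson
    distribution via ordered over-relaxation.  Chains start from an
    independent Poisson draw at the stimulus (tuning-component) rates.
    Returns (samples, n_rate_caps).
    """
    np.random.seed(seed)
    n = eta_stim.shape[0]
    y = np.empty(n, dtype=np.int64)
    for i in range(n):
        e = eta_stim[i]
        if e > MAX_LINPRED:
            e = MAX_LINPRED
        y[i] = _draw_count(np.exp(e), max_count)
    out = np.empty((n_samples, n), dtype=np.int64)
    order = np.arange(n)
    n_caps = 0
    for s in range(burn_in + n_samples):
        for k in range(n - 1, 0, -1):  # Fisher-Yates shuffle of update order
            j = int(np.random.random() * (k + 1))
            tmp = order[k]
            order[k] = order[j]
            order[j] = tmp
        for k in range(n):
            i = order[k]
            e = eta_stim[i]
            for j in range(n):
                e += beta[i, j] * y[j]
            if e > MAX_LINPRED:
                e = MAX_LINPRED
                n_caps += 1
            y[i] = _oor_update(y[i], np.exp(e), k_or, max_count)
        if s >= burn_in:
            for i in range(n):
                out[s - burn_in, i] = y[i]
    return out, n_caps


def ordered_overrelaxation_update(
    current_count: int,
    conditional_rate: float,
    k_or: int,
    seed: int | None = None,
    max_count: int | None = None,
) -> int:
    """One ordered over-relaxed update of a count variable.

    Draws ``k_or`` values from Poisson(conditional_rate), sorts them
    together with the current count, and returns the order statistic at
    the rank mirrored around the current value's rank (ties broken
    uniformly at random).  Leaves Poisson(conditional_rate) invariant
    while inducing negative serial dependence.
    """
    if conditional_rate <= 0:
        raise ValueError("conditional_rate must be positive")
    if seed is not None:
        np.random.seed(seed % 2**31)
    return int(
        _oor_update(
            np.int64(current_count),
            float(conditional_rate),
            int(k_or),
            -1 if max_count is None else int(max_count),
        )
    )


# ---------------------------------------------------------------------------
# Population parameter assembly
# ---------------------------------------------------------------------------


def _population_params(
    fits: list[ModelFit], stimulus_covariates: CovariateTable
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack per-neuron fits into (eta_stim[S, n], beta[n, n], neurons).

    ``eta_stim[s, i] = mu_i + alpha_i . f(x_s)`` and beta holds the fitted
    coupling weights (zero where a source is outside the decoded set).
    """
    fits = [f for f in fits if f is not None]
    neurons = np.array(sorted({f.neuron for f in fits}))
    index = {int(nn): k for k, nn in enumerate(neurons)}
    n = len(neurons)
    S = stimulus_covariates.n_trials
    eta = np.zeros((S, n))
    beta = np.zeros((n, n))
    for f in fits:
        i = index[int(f.neuron)]
        eta[:, i] = f.baseline
        if f.tuning_weights is not None and f.tuning_weights.size:
            if f.basis_spec is None:
                raise ValueError(f"fit for neuron {f.neuron} lacks a basis spec")
            F = build_basis(stimulus_covariates, f.basis_spec)
            eta[:, i] += F @ f.tuning_weights
        if f.coupling_weights is not None:
            for src, w in zip(f.coupling_sources, f.coupling_weights):
                if int(src) in index:
                    beta[i, index[int(src)]] = w
    return eta, beta, neurons


def _poisson_logpmf(y, rate, max_count: int | None):
    """log PMF, optionally renormalized over the truncated support."""
    rate = np.maximum(rate, 1e-12)
    lp = y * np.log(rate) - rate - gammaln(y + 1.0)
    if max_count is not None:
        ks = np.arange(max_count + 1)
        logz = logsumexp(
            ks[:, None] * np.log(rate).ravel()[None, :]
            - rate.ravel()[None, :]
            - gammaln(ks + 1.0)[:, None],
            axis=0,
        ).reshape(np.shape(rate))
        lp = lp - logz
    return lp


# ---------------------------------------------------------------------------
# Decoders
# ---------------------------------------------------------------------------


class TuningCurveDecoder(BaseEstimator, ClassifierMixin):
    """Conditional-independence Bayes decoder over a discrete stimulus set.

    Built from tuning-only encoding fits: the likelihood of a trial is the
    product over neurons of Poisson(y_i; lambda_i(s)) and the posterior is
    computed under a uniform prior.

    Parameters
    ----------
    fits : list of ModelFit
        Tuning-variant fits, one per decoded neuron.
    stimulus_covariates : CovariateTable
        One row per candidate stimulus.
    stimuli : array-like, optional
        Stimulus identifiers; defaults to the row index.
    """

    def __init__(self, fits=None, stimulus_covariates=None, stimuli=None):
        self.fits = fits
        self.stimulus_covariates = stimulus_covariates
        self.stimuli = stimuli

    def fit(self, X=None, y=None):
        eta, _, neurons = _population_params(self.fits, self.stimulus_covariates)
        self.rates_ = np.exp(np.minimum(eta, MAX_LINPRED))  # (S, n)
        if np.any(self.rates_ <= 0):
            raise ValueError("stimulus-conditioned rates must be positive")
        self.neurons_ = neurons
        self.classes_ = (
            np.arange(self.rates_.shape[0])
            if self.stimuli is None
            else np.asarray(self.stimuli)
        )
        return self

    def log_likelihood(self, X) -> np.ndarray:
        """(n_trials, S) log P(y | s), computed in log space."""
        Y = self._counts(X)
        ll = np.empty((Y.shape[0], self.rates_.shape[0]))
        for s in range(self.rates_.shape[0]):
            lp = Y * np.log(self.rates_[s]) - self.rates_[s] - gammaln(Y + 1.0)
            ll[:, s] = lp.sum(axis=1)
        return ll

    def predict_proba(self, X) -> np.ndarray:
        ll = self.log_likelihood(X)
        return np.exp(ll - logsumexp(ll, axis=1, keepdims=True))

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.log_likelihood(X), axis=1)]

    def posterior(self, X) -> PosteriorOverStimuli:
        return PosteriorOverStimuli(self.classes_, self.log_likelihood(X))

    def _counts(self, X) -> np.ndarray:
        if isinstance(X, SpikeCounts):
            X = X.counts
        Y = np.atleast_2d(np.asarray(X, dtype=float))
        if Y.shape[1] != len(self.neurons_):
            Y = Y[:, self.neurons_]
        return Y


class CoupledDecoder(BaseEstimator, ClassifierMixin):
    """Bayes decoder under the full instantaneous-coupling model.

    ``fit`` runs one Gibbs chain per candidate stimulus (the sampled joint
    depends only on the stimulus, so chains are reused across trials);
    ``predict_proba`` evaluates the chain-rule joint-probability estimator
    for each trial and stimulus and normalizes under the uniform prior.
    """

    def __init__(
        self, fits=None, stimulus_covariates=None, stimuli=None, config=None
    ):
        self.fits = fits
        self.stimulus_covariates = stimulus_covariates
        self.stimuli = stimuli
        self.config = config

    def fit(self, X=None, y=None):
        cfg = self.config or DecoderConfig()
        eta, beta, neurons = _population_params(self.fits, self.stimulus_covariates)
        self.eta_stim_ = eta
        self.beta_ = beta
        self.neurons_ = neurons
        self.classes_ = (
            np.arange(eta.shape[0]) if self.stimuli is None else np.asarray(self.stimuli)
        )
        mc = -1 if cfg.max_count is None else int(cfg.max_count)
        self.samples_ = []
        n_caps = 0
        for s in range(eta.shape[0]):
            samp, caps = _gibbs_chain(
                eta[s],
                beta,
                cfg.n_samples,
                cfg.burn_in,
                cfg.overrelax_order,
                mc,
                (cfg.seed + 7919 * s) % 2**31,
            )
            self.samples_.append(samp)
            n_caps += caps
        if n_caps:
            warnings.warn(
                f"{n_caps} conditional rates were capped during Gibbs sampling",
                RuntimeWarning,
            )
        self._max_count = cfg.max_count
        return self

    def log_likelihood(self, X) -> np.ndarray:
        Y = TuningCurveDecoder._counts(self, X)
        n_trials = Y.shape[0]
        S = self.eta_stim_.shape[0]
        ll = np.empty((n_trials, S))
        self.n_floored_ = 0
        for s in range(S):
            for t in range(n_trials):
                ll[t, s] = self._chain_rule(Y[t], s)
        return ll

    def _chain_rule(self, y: np.ndarray, s: int) -> float:
        """Chain-rule estimate of log P(y | s); neurons in ascending index
        order (fixed), not-yet-fixed neurons filled from the Gibbs samples."""
        samples = self.samples_[s]
        n = len(y)
        total = 0.0
        for i in range(n):
            eta = self.eta_stim_[s, i]
            if i > 0:
                eta = eta + self.beta_[i, :i] @ y[:i]
            if i < n - 1:
                eta_g = eta + samples[:, i + 1 :] @ self.beta_[i, i + 1 :]
            else:
                eta_g = np.full(samples.shape[0], eta)
            rates = np.exp(np.minimum(eta_g, MAX_LINPRED))
            lp = _poisson_logpmf(y[i], rates, self._max_count)
            marg = logsumexp(lp) - np.log(len(lp))
            if marg < np.log(1e-300):
                marg = np.log(1e-300)
                self.n_floored_ += 1
            total += marg
        return total

    def predict_proba(self, X) -> np.ndarray:
        ll = self.log_likelihood(X)
        return np.exp(ll - logsumexp(ll, axis=1, keepdims=True))

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.log_likelihood(X), axis=1)]

    def posterior(self, X) -> PosteriorOverStimuli:
        return PosteriorOverStimuli(self.classes_, self.log_likelihood(X))


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------


def decode_tc(
    trial_counts,
    tc_fits: list[ModelFit],
    stimulus_covariates: CovariateTable,
    stimuli=None,
) -> PosteriorOverStimuli:
    """Posterior over stimuli under the conditional-independence model."""
    dec = TuningCurveDecoder(tc_fits, stimulus_covariates, stimuli).fit()
    return dec.posterior(trial_counts)


def gibbs_sample_joint(
    full_fits: list[ModelFit],
    stimulus_covariates: CovariateTable,
    config: DecoderConfig | None = None,
    stimulus_index: int = 0,
) -> np.ndarray:
    """Gibbs samples of the population count vector under one stimulus."""
    cfg = config or DecoderConfig()
    eta, beta, _ = _population_params(full_fits, stimulus_covariates)
    mc = -1 if cfg.max_count is None else int(cfg.max_count)
    samples, caps = _gibbs_chain(
        eta[stimulus_index],
        beta,
        cfg.n_samples,
        cfg.burn_in,
        cfg.overrelax_order,
        mc,
        (cfg.seed + 7919 * stimulus_index) % 2**31,
    )
    if caps:
        warnings.warn(
            f"{caps} conditional rates were capped during Gibbs sampling",
            RuntimeWarning,
        )
    return samples


def chain_rule_joint_probability(
    observed_counts: np.ndarray,
    full_fits: list[ModelFit],
    stimulus_covariates: CovariateTable,
    samples: np.ndarray,
    stimulus_index: int = 0,
    max_count: int | None = None,
) -> float:
    """Chain-rule log-probability estimate of one observed count vector."""
    dec = CoupledDecoder(full_fits, stimulus_covariates)
    eta, beta, neurons = _population_params(full_fits, stimulus_covariates)
    dec.eta_stim_ = eta
    dec.beta_ = beta
    dec.neurons_ = neurons
    dec.samples_ = [samples] * (stimulus_index + 1)
    dec._max_count = max_count
    dec.n_floored_ = 0
    return float(
        dec._chain_rule(np.asarray(observed_counts, dtype=float), stimulus_index)
    )


def decode_full(
    trial_counts,
    full_fits: list[ModelFit],
    stimulus_covariates: CovariateTable,
    config: DecoderConfig | None = None,
    stimuli=None,
) -> PosteriorOverStimuli:
    """Posterior over stimuli under the full coupled model (Gibbs +
    chain-rule likelihood estimates, uniform prior)."""
    dec = CoupledDecoder(full_fits, stimulus_covariates, stimuli, config).fit()
    return dec.posterior(trial_counts)


def decoding_accuracy(posterior: PosteriorOverStimuli, true_labels) -> float:
    """Fraction of trials whose MAP stimulus matches the true label."""
    true_labels = np.asarray(true_labels)
    decoded = posterior.stimuli[posterior.decoded]
    return float(np.mean(decoded == true_labels))
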