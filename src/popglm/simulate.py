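"""Synthetic populations with known ground truth.

Everything the pipeline consumes can be generated here: cosine- or
RBF-tuned Poisson populations, toy coupled networks, LNP neurons driven by
equicorrelated Poisson input, the conditionally independent resimulation
control, and the within-condition shuffle control.

Correlated Poisson variates use a Gaussian copula: equicorrelated latent
normals are pushed through the Poisson quantile function, so every margin
is exactly Poisson(mean) (variance equal to the mean) while all pairs share
one count-scale correlation.  The latent correlation is calibrated to the
requested count correlation by bisection on a Gauss-Hermite quadrature of
the copula cross-moment.

Populations with instantaneous coupling have no product-form joint
distribution; their ground-truth joint is defined as the law produced by a
short Gibbs pass (default 20 sweeps) over the coupled conditionals, seeded
from the uncoupled draw, with a fixed random neuron order per trial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from functools import lru_cache

import numpy as np
from numba import njit
from scipy import stats

from .basis import BasisSpec, build_basis
from .data import CovariateTable, SpikeCounts

__all__ = [
    "PopulationSpec",
    "CorrelatedInputSpec",
    "simulate_tuned_population",
    "sample_correlated_poisson",
    "latent_correlation",
    "count_correlation_from_latent",
    "simulate_lnp_with_correlated_input",
    "simulate_from_tuning_model",
    "shuffle_within_condition",
    "toy_chain_spec",
]

MAX_LINPRED = 30.0

_TUNING_TO_BASIS = {
    "cosine": "cosine_direction",
    "cosine+speed": "cosine_direction_plus_speed",
    "rbf2d": "rbf_grid_2d",
    "rbf_logfreq": "rbf_logfreq",
}


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass
class PopulationSpec:
    """Ground-truth description of a simulated population.

    Rates follow lambda_it = exp(mu_i + alpha_i . f(x_t) + g*(z_it - 1)
    + sum_j beta_ij y_jt) where f is the tuning basis, z_it an optional
    equicorrelated Poisson common input (mean 1, correlation
    ``common_input_rho``) and beta the coupling matrix (zero diagonal).

    When ``mu``/``alpha`` are not given they are sampled once from
    ``rate_range`` (baseline rates in Hz, uniform on the log scale) and
    ``alpha_scale`` (uniform tuning-vector norm, random preferred
    stimulus), which emulates the heterogeneous tuning of cortical
    recordings.
    """

    n_neurons: int
    n_trials: int
    bin_duration: float = 0.2
    tuning_kind: str = "cosine"  # cosine | cosine+speed | rbf2d | rbf_logfreq | none
    condition_set: np.ndarray | None = None
    mu: np.ndarray | None = None
    alpha: np.ndarray | None = None
    coupling: np.ndarray | None = None
    common_input_rho: float = 0.0
    common_input_gain: float = 0.5
    rate_range: tuple[float, float] = (2.0, 10.0)
    alpha_scale: tuple[float, float] = (0.5, 1.5)
    gibbs_sweeps: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 1 or self.n_trials < 1:
            raise ValueError("n_neurons and n_trials must be >= 1")
        if self.bin_duration <= 0:
            raise ValueError("bin_duration must be positive")
        if not (0.0 <= self.common_input_rho < 1.0):
            raise ValueError("common_input_rho must be in [0, 1)")
        if self.coupling is not None:
            self.coupling = np.asarray(self.coupling, dtype=float)
            if self.coupling.shape != (self.n_neurons, self.n_neurons):
                raise ValueError("coupling must be (n_neurons, n_neurons)")
            if np.any(np.diag(self.coupling) != 0):
                raise ValueError("coupling diagonal (self-coupling) must be zero")
        if self.tuning_kind not in (*_TUNING_TO_BASIS, "none"):
            raise ValueError(f"unknown tuning_kind {self.tuning_kind!r}")

    def basis_spec(self) -> BasisSpec | None:
        if self.tuning_kind == "none":
            return None
        return BasisSpec(kind=_TUNING_TO_BASIS[self.tuning_kind])

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return d


@dataclass
class CorrelatedInputSpec:
    """Equicorrelated Poisson inputs feeding one LNP output neuron.

    ``sparseness`` is the probability that an input's weight is zero; the
    nonzero weights share one positive value, scaled so the output's mean
    linear predictor sits near log(5) counts per bin (kept well clear of
    overflow).
    """

    n_inputs: int
    rho: float = 0.0
    mean: float = 1.0
    sparseness: float = 0.0
    weight_value: float | None = None
    total_gain: float = 1.0
    mu0: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_inputs < 1:
            raise ValueError("n_inputs must be >= 1")
        if self.mean <= 0:
            raise ValueError("mean must be positive")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must be in [0, 1)")
        if not (0.0 <= self.sparseness <= 1.0):
            raise ValueError("sparseness must be in [0, 1]")


# ---------------------------------------------------------------------------
# Correlated Poisson via a Gaussian copula
# ---------------------------------------------------------------------------


def _clip_cdf(u: np.ndarray) -> np.ndarray:
    # Phi(z) rounds to 1.0 in double precision for z > ~8, which would push
    # the Poisson quantile to +inf; clip inside the open unit interval.
    return np.clip(u, 1e-16, 1.0 - 1e-16)


@lru_cache(maxsize=64)
def _poisson_thresholds(mean: float) -> np.ndarray:
    """Latent thresholds z_k = Phi^{-1}(F_Poisson(k-1; mean)) for k >= 1.

    The copula transform is the tail sum g(z) = #{k >= 1 : z > z_k};
    thresholds with negligible upper tail mass are dropped.
    """
    kmax = int(stats.poisson.ppf(1.0 - 1e-13, mean)) + 1
    cdf = stats.poisson.cdf(np.arange(kmax), mean)
    return stats.norm.ppf(_clip_cdf(cdf[cdf < 1.0 - 1e-14]))


def count_correlation_from_latent(r: float, mean: float) -> float:
    """Count-scale Pearson correlation induced by latent normal correlation r.

    Uses the tail-sum identity E[g(Z1) g(Z2)] = sum_{k,l} P(Z1 > z_k,
    Z2 > z_l) with g the Poisson quantile transform, evaluated with the
    bivariate normal CDF; margins are exactly Poisson(mean), so the
    variance in the denominator is the mean.
    """
    if r == 0.0:
        return 0.0
    zk = _poisson_thresholds(mean)
    a, b = np.meshgrid(zk, zk, indexing="ij")
    pts = np.column_stack([a.ravel(), b.ravel()])
    bvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, r], [r, 1.0]])
    joint_cdf = bvn.cdf(pts).reshape(a.shape)
    tail = 1.0 - stats.norm.cdf(a) - stats.norm.cdf(b) + joint_cdf
    exy = float(tail.sum())
    return (exy - mean * mean) / mean


@lru_cache(maxsize=64)
def latent_correlation(rho: float, mean: float, tol: float = 1e-6) -> float:
    """Latent normal correlation giving count correlation ``rho`` (bisection).

    The count correlation is monotone increasing in the latent correlation
    and never exceeds it, so bisection on [rho, 1) brackets the root.
    """
    if rho == 0.0:
        return 0.0
    lo, hi = 0.0, 1.0 - 1e-9
    if count_correlation_from_latent(hi, mean) < rho:
        raise ValueError(f"count correlation {rho} unattainable for mean {mean}")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if count_correlation_from_latent(mid, mean) < rho:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def sample_correlated_poisson(
    spec: CorrelatedInputSpec,
    n_draws: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw (n_draws, n_inputs) equicorrelated Poisson counts.

    Margins are exactly Poisson(spec.mean) — variance equal to the mean —
    and every pair of columns has count correlation spec.rho (covariance
    mean * [(1 - rho) I + rho J]).
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    r = latent_correlation(float(spec.rho), float(spec.mean))
    shared = rng.standard_normal((n_draws, 1))
    indep = rng.standard_normal((n_draws, spec.n_inputs))
    z = np.sqrt(r) * shared + np.sqrt(1.0 - r) * indep
    counts = stats.poisson.ppf(_clip_cdf(stats.norm.cdf(z)), spec.mean)
    return counts.astype(np.int64)


# ---------------------------------------------------------------------------
# Tuned populations (optionally coupled, optionally with common input)
# ---------------------------------------------------------------------------


def _default_conditions(kind: str) -> np.ndarray | None:
    if kind in ("cosine", "cosine+speed", "none"):
        return np.arange(8) * 45.0  # 8 targets / grating directions
    if kind == "rbf_logfreq":
        return np.linspace(0.0, 6.4, 7)  # tone set over 6.4 octaves
    return None  # rbf2d: continuous foraging positions


def _draw_covariates(spec: PopulationSpec, rng: np.random.Generator):
    """Per-trial covariates, condition labels, and the tuning block."""
    kind = spec.tuning_kind
    conds = spec.condition_set
    if conds is None:
        conds = _default_conditions(kind)
    labels = None
    import pandas as pd

    if kind in ("cosine", "cosine+speed", "none"):
        conds = np.asarray(conds, dtype=float)
        reps = int(np.ceil(spec.n_trials / conds.size))
        labels = np.tile(np.arange(conds.size), reps)[: spec.n_trials]
        rng.shuffle(labels)
        df = pd.DataFrame({"direction": conds[labels]})
        if kind == "cosine+speed":
            df["speed"] = rng.uniform(5.0, 25.0, spec.n_trials)
    elif kind == "rbf_logfreq":
        conds = np.asarray(conds, dtype=float)
        reps = int(np.ceil(spec.n_trials / conds.size))
        labels = np.tile(np.arange(conds.size), reps)[: spec.n_trials]
        rng.shuffle(labels)
        df = pd.DataFrame({"log_frequency": conds[labels]})
    else:  # rbf2d: free foraging, continuous positions in a 180 cm arena
        df = pd.DataFrame(
            {
                "pos_x": rng.uniform(0.0, 180.0, spec.n_trials),
                "pos_y": rng.uniform(0.0, 180.0, spec.n_trials),
            }
        )
    cov = CovariateTable(df)
    bspec = spec.basis_spec()
    F = build_basis(cov, bspec) if bspec is not None else np.empty((spec.n_trials, 0))
    return cov, labels, F, bspec


def _materialize_params(spec: PopulationSpec, K: int, rng: np.random.Generator):
    if spec.mu is None:
        lo, hi = spec.rate_range
        rates = np.exp(rng.uniform(np.log(lo), np.log(hi), spec.n_neurons))
        mu = np.log(rates * spec.bin_duration)
    else:
        mu = np.broadcast_to(np.asarray(spec.mu, dtype=float), (spec.n_neurons,)).copy()
    if K == 0:
        alpha = np.empty((spec.n_neurons, 0))
    elif spec.alpha is None:
        a = rng.standard_normal((spec.n_neurons, K))
        norms = np.linalg.norm(a, axis=1, keepdims=True)
        scale = rng.uniform(*spec.alpha_scale, (spec.n_neurons, 1))
        alpha = a / np.maximum(norms, 1e-12) * scale
    else:
        alpha = np.asarray(spec.alpha, dtype=float).reshape(spec.n_neurons, K)
    return mu, alpha


def _topological_order(coupling: np.ndarray) -> list[int] | None:
    """Kahn topological sort of the coupling graph (edge j -> i when
    coupling[i, j] != 0); None if the graph has a directed cycle."""
    n = coupling.shape[0]
    adj = coupling != 0
    indeg = adj.sum(axis=1).astype(int)  # number of inputs per neuron
    ready = [i for i in range(n) if indeg[i] == 0]
    order: list[int] = []
    while ready:
        j = ready.pop()
        order.append(j)
        for i in np.flatnonzero(adj[:, j]):
            indeg[i] -= 1
            if indeg[i] == 0:
                ready.append(int(i))
    return order if len(order) == n else None


@njit(cache=True)
def _gibbs_pass(eta0, beta, orders, n_sweeps, y, seed):
    """In-place Gibbs sweeps over coupled conditionals; trials independent.

    Returns (-1, -1) on success, else the (trial, neuron) whose linear
    predictor exceeded the overflow cap.
    """
    np.random.seed(seed)
    n_trials, n = eta0.shape
    for t in range(n_trials):
        for _s in range(n_sweeps):
            for k in range(n):
                i = orders[t, k]
                e = eta0[t, i]
                for j in range(n):
                    e += beta[i, j] * y[t, j]
                if e > MAX_LINPRED:
                    return t, i
                y[t, i] = np.random.poisson(np.exp(e))
    return -1, -1


def simulate_tuned_population(
    spec: PopulationSpec,
) -> tuple[SpikeCounts, CovariateTable]:
    """Simulate trial counts from the ground-truth population model.

    With zero coupling and no common input the neurons are conditionally
    independent Poisson given the covariates.  With coupling, counts come
    from a short Gibbs pass over the coupled conditionals (see module
    docstring).
    """
    rng = np.random.default_rng(spec.seed)
    cov, labels, F, _ = _draw_covariates(spec, rng)
    mu, alpha = _materialize_params(spec, F.shape[1], rng)
    # record the realised ground truth on the spec for later comparison
    spec.mu, spec.alpha = mu, alpha
    eta0 = mu[None, :] + F @ alpha.T
    if spec.common_input_rho > 0 and spec.common_input_gain != 0:
        zspec = CorrelatedInputSpec(
            n_inputs=spec.n_neurons, rho=spec.common_input_rho, mean=1.0
        )
        z = sample_correlated_poisson(zspec, spec.n_trials, rng)
        eta0 = eta0 + spec.common_input_gain * (z - 1.0)
    if np.any(eta0 > MAX_LINPRED):
        t, i = np.argwhere(eta0 > MAX_LINPRED)[0]
        raise OverflowError(
            f"linear predictor exceeds {MAX_LINPRED} for neuron {i} on trial {t}"
        )
    y = rng.poisson(np.exp(eta0)).astype(np.int64)
    if spec.coupling is not None and np.any(spec.coupling != 0):
        topo = _topological_order(spec.coupling)
        if topo is not None:
            # Feed-forward coupling graph: the directed joint is exact —
            # sample neurons in topological order, each conditioned on its
            # already-sampled inputs (vectorized across trials).
            for i in topo:
                eta = eta0[:, i] + y @ spec.coupling[i]
                if np.any(eta > MAX_LINPRED):
                    t = int(np.argmax(eta > MAX_LINPRED))
                    raise OverflowError(
                        f"linear predictor exceeds {MAX_LINPRED} for neuron "
                        f"{i} on trial {t}"
                    )
                y[:, i] = rng.poisson(np.exp(eta))
        else:
            # Recurrent coupling: no product-form joint; define the ground
            # truth by a brief Gibbs pass over the coupled conditionals.
            orders = np.empty((spec.n_trials, spec.n_neurons), dtype=np.int64)
            for t in range(spec.n_trials):
                orders[t] = rng.permutation(spec.n_neurons)
            gibbs_seed = int(rng.integers(2**31 - 1))
            t, i = _gibbs_pass(
                eta0, spec.coupling, orders, spec.gibbs_sweeps, y, gibbs_seed
            )
            if t >= 0:
                raise OverflowError(
                    f"linear predictor exceeds {MAX_LINPRED} for neuron {i} "
                    f"on trial {t} during the coupling Gibbs pass"
                )
    counts = SpikeCounts(y, spec.bin_duration, condition_labels=labels)
    return counts, cov


def toy_chain_spec(
    n_trials: int = 4000,
    beta: float = 0.25,
    seed: int = 0,
    bin_duration: float = 0.2,
) -> PopulationSpec:
    """Three-neuron chain: only neuron 0 is tuned; 1 and 2 receive its output.

    Neuron 0 carries von-Mises-shaped direction tuning (the cosine model's
    exponentiated cosine); neurons 1 and 2 have flat tuning but positive
    coupling from neuron 0, so their apparent tuning is inherited entirely
    through the coupling — the "explaining away" toy network.
    """
    coupling = np.zeros((3, 3))
    coupling[1, 0] = beta
    coupling[2, 0] = beta
    return PopulationSpec(
        n_neurons=3,
        n_trials=n_trials,
        bin_duration=bin_duration,
        tuning_kind="cosine",
        mu=np.array([np.log(2.0), np.log(1.0), np.log(1.0)]),
        alpha=np.array([[1.2, 0.0], [0.0, 0.0], [0.0, 0.0]]),
        coupling=coupling,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# LNP neuron with correlated input (scaling simulations)
# ---------------------------------------------------------------------------


@dataclass
class LNPSimulation:
    """Inputs, output and ground-truth weights of one correlated-input run."""

    inputs: np.ndarray  # (n_draws, n_inputs) Poisson counts
    outputs: SpikeCounts  # (n_draws, 1)
    weights: np.ndarray  # (n_inputs,) with exact zeros where pruned
    mu0: float


def simulate_lnp_with_correlated_input(
    spec: CorrelatedInputSpec,
    n_draws: int,
    bin_duration: float = 0.1,
) -> LNPSimulation:
    """One LNP output neuron driven by equicorrelated Poisson inputs.

    Output counts are Poisson(exp(mu0 + w . z_t)).  Weights are a sparse
    binary vector (zero with probability ``sparseness``) with one shared
    positive value; by default the value and baseline are scaled so the
    mean linear predictor is log(5) per bin.
    """
    rng = np.random.default_rng(spec.seed)
    z = sample_correlated_poisson(spec, n_draws, rng)
    nonzero = rng.random(spec.n_inputs) >= spec.sparseness
    k = max(int(nonzero.sum()), 1)
    if spec.weight_value is None:
        wval = spec.total_gain / (k * spec.mean)
    else:
        wval = float(spec.weight_value)
    w = np.where(nonzero, wval, 0.0)
    mu0 = float(np.log(5.0) - w.sum() * spec.mean) if spec.mu0 is None else spec.mu0
    eta = mu0 + z @ w
    if np.any(eta > MAX_LINPRED):
        t = int(np.argmax(eta > MAX_LINPRED))
        raise OverflowError(
            f"linear predictor exceeds {MAX_LINPRED} for the output neuron "
            f"on draw {t}"
        )
    y = rng.poisson(np.exp(eta)).astype(np.int64)
    return LNPSimulation(
        inputs=z,
        outputs=SpikeCounts(y[:, None], bin_duration),
        weights=w,
        mu0=mu0,
    )


# ---------------------------------------------------------------------------
# Controls
# ---------------------------------------------------------------------------


def simulate_from_tuning_model(
    fits: list,
    covariates: CovariateTable,
    seed: int = 0,
    bin_duration: float | None = None,
    condition_labels: np.ndarray | None = None,
) -> SpikeCounts:
    """Resimulate counts from fitted tuning-only models.

    The resulting population is conditionally independent given the
    covariates by construction — the over-fitting control: any apparent
    coupling recovered from these data is spurious.
    """
    rng = np.random.default_rng(seed)
    rates = []
    for fit in fits:
        if fit.variant != "tuning":
            raise ValueError(
                f"simulate_from_tuning_model needs tuning-only fits, got "
                f"{fit.variant!r} for neuron {fit.neuron}"
            )
        eta = np.full(covariates.n_trials, fit.baseline)
        if fit.basis_spec is not None and fit.tuning_weights is not None and fit.tuning_weights.size:
            eta = eta + build_basis(covariates, fit.basis_spec) @ fit.tuning_weights
        rates.append(np.exp(np.minimum(eta, MAX_LINPRED)))
    y = rng.poisson(np.column_stack(rates)).astype(np.int64)
    if bin_duration is None:
        bin_duration = 0.2
    return SpikeCounts(y, bin_duration, condition_labels=condition_labels)


def shuffle_within_condition(counts: SpikeCounts, seed: int = 0) -> SpikeCounts:
    """Permute trials within each condition, independently per neuron.

    Destroys noise correlations while preserving, exactly, each neuron's
    per-condition count multiset (hence its tuning curve) and therefore all
    stimulus correlations.  A condition with fewer than 2 trials is left
    untouched (warning).
    """
    if counts.condition_labels is None:
        raise ValueError("shuffle_within_condition requires condition labels")
    rng = np.random.default_rng(seed)
    y = counts.counts.copy()
    for cond in np.unique(counts.condition_labels):
        idx = np.flatnonzero(counts.condition_labels == cond)
        if idx.size < 2:
            warnings.warn(
                f"condition {cond!r} has {idx.size} trial(s); shuffle is a no-op",
                RuntimeWarning,
            )
            continue
        for j in range(counts.n_neurons):
            y[idx, j] = y[rng.permutation(idx), j]
    return SpikeCounts(y, counts.bin_duration, counts.condition_labels.copy())
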