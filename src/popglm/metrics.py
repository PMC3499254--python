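"""Population summary statistics.

Spike-prediction accuracy (cross-validated log-likelihood ratio against a
homogeneous Poisson process, in bits/s), the fraction of spiking variance
attributed to tuning in the full model, tuning modulation / preference /
overlap, Pearson spike-count correlations, coupling degree distributions,
and hyperbolic fits of accuracy-versus-population-size curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .basis import BasisSpec, basis_grid, build_basis
from .data import SpikeCounts
from .glm import DesignMatrix, ModelFit, fit_glm, poisson_log_likelihood

__all__ = [
    "spike_prediction_accuracy",
    "fraction_variance_tuning",
    "tuning_modulation",
    "tuning_preference",
    "tuning_overlap",
    "overlap_matrix",
    "spike_count_correlation",
    "noise_correlation",
    "circular_correlation",
    "degree_summary",
    "NetworkSummary",
    "HyperbolicFit",
    "fit_hyperbolic",
    "ScalingCurve",
]

LOG2 = np.log(2.0)


# ---------------------------------------------------------------------------
# Spike prediction accuracy
# ---------------------------------------------------------------------------


def spike_prediction_accuracy(
    fit: ModelFit,
    counts_for_neuron: np.ndarray,
    design: DesignMatrix,
    bin_duration: float,
    folds: list | None = None,
) -> float:
    """Log-likelihood ratio vs a homogeneous Poisson process, in bits/s.

    Without folds the fit is evaluated in sample against the in-sample
    mean-rate null, so the intercept-only model scores exactly 0.  With
    folds, both the model (at the fit's penalty) and the homogeneous null
    are refit on each training split and evaluated held-out — the
    cross-validated spike-prediction accuracy.  The base-2 log ratio is
    divided by the total covered time, n_trials * bin_duration.
    """
    y = np.asarray(counts_for_neuron, dtype=float)
    total_time = len(y) * bin_duration
    if folds is None:
        ll_model = poisson_log_likelihood(y, fit.rates(design))
        ll_null = poisson_log_likelihood(y, np.full_like(y, max(y.mean(), 1e-12)))
        return (ll_model - ll_null) / LOG2 / total_time
    llr = 0.0
    for train, test in folds:
        sub_design = _subset_design(design, train)
        refit = fit_glm(
            y[train],
            sub_design,
            fit.variant,
            penalty=fit.penalty,
            tc_penalty_fraction=fit.tc_penalty_fraction,
            basis_spec=fit.basis_spec,
        )
        test_design = _subset_design(design, test)
        ll_model = poisson_log_likelihood(y[test], refit.rates(test_design))
        null_rate = max(y[train].mean(), 1e-12)
        ll_null = poisson_log_likelihood(y[test], np.full(len(test), null_rate))
        llr += ll_model - ll_null
    return llr / LOG2 / total_time


def _subset_design(design: DesignMatrix, idx) -> DesignMatrix:
    return DesignMatrix(
        design.tuning_block[idx],
        design.coupling_block[idx],
        design.coupling_sources,
        target=design.target,
    )


# ---------------------------------------------------------------------------
# Variance partition
# ---------------------------------------------------------------------------


def fraction_variance_tuning(full_fit: ModelFit, design: DesignMatrix) -> float:
    """Share of linear-predictor variance carried by the tuning component.

    Var_t(tuning component) / [Var_t(tuning) + Var_t(coupling)] over
    trials.  1 means coupling adds nothing beyond tuning; 0 means the
    stimulus dependence is carried entirely by the coupling terms.  NaN
    (missing) when both components are flat.
    """
    if full_fit.variant != "full":
        raise ValueError(
            f"fraction_variance_tuning needs a full-model fit, got "
            f"{full_fit.variant!r}"
        )
    tun = design.tuning_block @ full_fit.tuning_weights
    cpl = design.coupling_block @ full_fit.coupling_weights
    vt = float(np.var(tun))
    vc = float(np.var(cpl))
    if vt + vc == 0.0:
        return float("nan")
    return vt / (vt + vc)


# ---------------------------------------------------------------------------
# Tuning summaries
# ---------------------------------------------------------------------------


def _tuning_component(fit: ModelFit, basis_spec: BasisSpec, grid) -> np.ndarray:
    F = build_basis(grid, basis_spec)
    return fit.baseline + F @ fit.tuning_weights


def tuning_modulation(
    fit: ModelFit,
    basis_spec: BasisSpec,
    bin_duration: float,
    conditions=None,
    n_grid: int = 512,
) -> float:
    """Peak-to-peak firing-rate range of the tuning component, in Hz.

    Evaluates exp(mu + alpha . f(x)) either at the experiment's discrete
    conditions (e.g. the 8 reach targets) or over a dense stimulus grid.
    """
    if fit.tuning_weights is None:
        raise ValueError("fit has no tuning weights")
    grid = conditions if conditions is not None else basis_grid(basis_spec, n_grid)
    eta = _tuning_component(fit, basis_spec, grid)
    rate = np.exp(eta)
    return float((rate.max() - rate.min()) / bin_duration)


def tuning_preference(
    fit: ModelFit, basis_spec: BasisSpec, n_grid: int = 512
) -> float:
    """Preferred stimulus of the tuning component.

    Cosine bases: preferred direction atan2(alpha_sin, alpha_cos) in
    degrees [0, 360).  Log-frequency RBFs: preferred frequency in Hz
    (tone set anchored at 180 Hz).  2-D place RBFs: preferred place along
    the x-axis in cm.  Flat tuning (alpha = 0) is undefined -> NaN.
    """
    a = fit.tuning_weights
    if a is None or np.allclose(a, 0.0):
        return float("nan")
    if basis_spec.kind in ("cosine_direction", "cosine_direction_plus_speed"):
        return float(np.rad2deg(np.arctan2(a[1], a[0])) % 360.0)
    grid = basis_grid(basis_spec, n_grid)
    eta = _tuning_component(fit, basis_spec, grid)
    k = int(np.argmax(eta))
    if basis_spec.kind == "rbf_logfreq":
        octave = grid["log_frequency"][k]
        return float(180.0 * 2.0**octave)  # Hz
    return float(grid["pos_x"][k])  # cm


def tuning_overlap(alpha_i: np.ndarray, alpha_j: np.ndarray) -> float:
    """Cosine similarity of two tuning weight vectors (baseline excluded).

    1 = identical tuning up to baseline, 0 = orthogonal tuning, -1 =
    exactly opposite tuning (e.g. cosine-tuned neurons 180 degrees apart).
    Undefined (NaN) if either vector is zero.
    """
    ai = np.asarray(alpha_i, dtype=float)
    aj = np.asarray(alpha_j, dtype=float)
    if ai.shape != aj.shape:
        raise ValueError("tuning vectors must share the basis")
    ni, nj = np.linalg.norm(ai), np.linalg.norm(aj)
    if ni == 0.0 or nj == 0.0:
        return float("nan")
    return float(np.dot(ai, aj) / (ni * nj))


def overlap_matrix(alphas: np.ndarray) -> np.ndarray:
    """Pairwise tuning overlaps for rows of an (n_neurons, K) weight array."""
    alphas = np.atleast_2d(np.asarray(alphas, dtype=float))
    n = alphas.shape[0]
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = tuning_overlap(alphas[i], alphas[j])
    return out


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------


def spike_count_correlation(counts: SpikeCounts | np.ndarray) -> np.ndarray:
    """Pearson correlation of trial-by-trial counts across all trials.

    Symmetric with unit diagonal; pairs involving a zero-variance neuron
    are NaN (missing) off the diagonal.
    """
    y = counts.counts if isinstance(counts, SpikeCounts) else np.asarray(counts)
    y = y.astype(float)
    if y.shape[0] < 2:
        raise ValueError("need at least 2 trials")
    sd = y.std(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = np.corrcoef(y, rowvar=False)
    r = np.atleast_2d(r)
    bad = sd == 0
    r[bad, :] = np.nan
    r[:, bad] = np.nan
    np.fill_diagonal(r, 1.0)
    return r


def noise_correlation(counts: SpikeCounts) -> np.ndarray:
    """Within-condition (noise) correlation: counts are mean-centered per
    condition before the Pearson correlation, removing stimulus
    correlations."""
    if counts.condition_labels is None:
        raise ValueError("noise_correlation requires condition labels")
    y = counts.counts.astype(float).copy()
    for cond in np.unique(counts.condition_labels):
        idx = counts.condition_labels == cond
        y[idx] -= y[idx].mean(axis=0)
    return spike_count_correlation(y)


def circular_correlation(a_deg, b_deg) -> float:
    """Fisher-Lee circular correlation of two paired angle samples.

    For comparing preferred directions between models; use the plain
    Pearson correlation for linear preferences (frequency, place).
    """
    a = np.deg2rad(np.asarray(a_deg, dtype=float))
    b = np.deg2rad(np.asarray(b_deg, dtype=float))
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    abar = np.arctan2(np.sin(a).sum(), np.cos(a).sum())
    bbar = np.arctan2(np.sin(b).sum(), np.cos(b).sum())
    sa, sb = np.sin(a - abar), np.sin(b - bbar)
    denom = np.sqrt((sa**2).sum() * (sb**2).sum())
    if denom == 0:
        return float("nan")
    return float((sa * sb).sum() / denom)


# ---------------------------------------------------------------------------
# Degrees
# ---------------------------------------------------------------------------


@dataclass
class NetworkSummary:
    """Functional-connectivity degrees from a set of population fits."""

    neurons: np.ndarray
    in_degree: np.ndarray  # nonzero incoming couplings per neuron
    out_degree: np.ndarray  # times a neuron's count carries nonzero weight
    coupling_matrix: np.ndarray  # [target, source] fitted weights
    correlation_matrix: np.ndarray | None = None


def degree_summary(
    fits: list[ModelFit], counts: SpikeCounts | None = None
) -> NetworkSummary:
    """In/out degrees over the nonzero fitted coupling weights.

    Exact zeros from L1 soft-thresholding define "no coupling"; no epsilon
    threshold is applied.  sum(in_degree) == sum(out_degree) == number of
    nonzero couplings by construction.
    """
    fits = [f for f in fits if f is not None]
    if not fits:
        raise ValueError("no fits supplied")
    neurons = np.array(sorted({f.neuron for f in fits}))
    index = {n: k for k, n in enumerate(neurons)}
    n = len(neurons)
    W = np.zeros((n, n))
    for f in fits:
        if f.coupling_weights is None:
            raise ValueError(
                f"fit for neuron {f.neuron} ({f.variant!r}) has no coupling block"
            )
        for src, w in zip(f.coupling_sources, f.coupling_weights):
            if src in index:
                W[index[f.neuron], index[src]] = w
    nz = W != 0
    corr = spike_count_correlation(counts) if counts is not None else None
    return NetworkSummary(
        neurons=neurons,
        in_degree=nz.sum(axis=1),
        out_degree=nz.sum(axis=0),
        coupling_matrix=W,
        correlation_matrix=corr,
    )


# ---------------------------------------------------------------------------
# Hyperbolic scaling
# ---------------------------------------------------------------------------


@dataclass
class HyperbolicFit:
    """f(n) = f_max * n / (n + n_half)."""

    f_max: float
    n_half: float
    near_linear: bool  # n_half beyond the largest measured size

    def __call__(self, n) -> np.ndarray:
        n = np.asarray(n, dtype=float)
        return self.f_max * n / (n + self.n_half)


def fit_hyperbolic(sizes, values) -> HyperbolicFit | None:
    """Least-squares hyperbola through (size, value) points, multi-start.

    Saturating growth from zero toward f_max with half-saturation n_half.
    When the data are still rising linearly at the largest size the fitted
    n_half exceeds it and the result is flagged ``near_linear``.  Returns
    None if no start converges.
    """
    sizes = np.asarray(sizes, dtype=float)
    values = np.asarray(values, dtype=float)
    if sizes.size < 3:
        raise ValueError("need at least 3 sizes")
    if np.any(np.diff(sizes) <= 0):
        raise ValueError("sizes must be strictly increasing")

    def hyp(n, fmax, nhalf):
        return fmax * n / (n + nhalf)

    vmax = max(values.max(), 1e-12)
    best = None
    for nh0 in np.geomspace(sizes.min(), 10 * sizes.max(), 5):
        try:
            popt, _ = curve_fit(
                hyp,
                sizes,
                values,
                p0=[vmax, nh0],
                bounds=([0.0, 1e-6], [np.inf, np.inf]),
                maxfev=10000,
            )
        except RuntimeError:
            continue
        sse = float(np.sum((hyp(sizes, *popt) - values) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        return None
    f_max, n_half = best[1]
    return HyperbolicFit(
        f_max=float(f_max),
        n_half=float(n_half),
        near_linear=bool(n_half > sizes.max()),
    )


@dataclass
class ScalingCurve:
    """Mean metric (accuracy or variance fraction) versus population size."""

    sizes: np.ndarray
    values: np.ndarray  # mean per size
    sem: np.ndarray
    hyperbolic: HyperbolicFit | None = None

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes)
        if np.any(np.diff(self.sizes) <= 0):
            raise ValueError("sizes must be strictly increasing")

    def fit(self) -> "ScalingCurve":
        try:
            self.hyperbolic = fit_hyperbolic(self.sizes, self.values)
        except (ValueError, RuntimeError):
            self.hyperbolic = None
        return self
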