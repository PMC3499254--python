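"""Linear-nonlinear-Poisson encoding models with L1-penalized coupling.

Each neuron's trial count y_it is modelled as Poisson with rate

    lambda_it = exp( mu_i + alpha_i . f(x_t) + sum_{j != i} beta_ij y_jt )

where f(x_t) is a tuning basis (``popglm.basis``) evaluated on the external
covariates and the beta_ij couple the neuron to the *same-bin* counts of the
other observed neurons.  Three nested variants are fit per neuron:

- ``tuning``   — basis terms only (the classical tuning-curve model),
- ``coupling`` — other neurons' counts only,
- ``full``     — both, letting coupling "explain away" apparent tuning.

Fitting maximizes the Poisson log-likelihood minus an L1 penalty on the
coupling weights (MAP with a Laplace prior); cosine tuning weights are left
unpenalized while radial-basis tuning weights receive a small fraction of
the coupling penalty to stabilise the expansion.  The solver is a
glmnet-style proximal Newton: an outer quadratic approximation (IRLS) with
cyclical coordinate descent and soft-thresholding on the inner weighted
least-squares problem, plus step halving so the penalized objective never
decreases.  The penalty is chosen by 10-fold cross-validated held-out
log-likelihood over a log-spaced path starting at the smallest penalty that
zeroes every coupling weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.special import gammaln
from sklearn.base import BaseEstimator
from sklearn.model_selection import KFold

from .basis import BasisSpec, build_basis
from .data import CovariateTable, SpikeCounts

__all__ = [
    "PoissonGLM",
    "DesignMatrix",
    "ModelFit",
    "build_design",
    "fit_glm",
    "select_penalty",
    "penalty_path",
    "fit_population",
    "poisson_log_likelihood",
]

VARIANTS = ("tuning", "coupling", "full")

# Linear predictors are capped here; a cap means the likelihood surface is
# flat in some direction (separation) and the weights are no longer MLEs.
MAX_LINPRED = 30.0


class ConvergenceError(RuntimeError):
    """Raised when the proximal-Newton solver fails to converge."""


# ---------------------------------------------------------------------------
# Numba solver kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _penalized_objective(X, y, w, b, cj, lam):
    n = X.shape[0]
    p = X.shape[1]
    obj = 0.0
    for t in range(n):
        eta = b
        for j in range(p):
            eta += X[t, j] * w[j]
        if eta > MAX_LINPRED:
            eta = MAX_LINPRED
        obj += y[t] * eta - np.exp(eta)
    for j in range(p):
        obj -= lam * cj[j] * abs(w[j])
    return obj


@njit(cache=True)
def _intercept_step(r, wt, sw, n):
    db = 0.0
    for t in range(n):
        db += wt[t] * r[t]
    db /= sw
    for t in range(n):
        r[t] -= db
    return db


@njit(cache=True)
def _cd_pass(X, r, wt, a, cj, lam, w_new, active, active_only, n, p):
    """One cyclical soft-thresholding pass.

    Returns the quadratic-objective gain of the pass (sum of a_j d_j^2),
    used as the inner stopping criterion.
    """
    gain = 0.0
    for j in range(p):
        if active_only and not active[j]:
            continue
        if a[j] <= 0.0:
            continue
        g = a[j] * w_new[j]
        for t in range(n):
            g += wt[t] * X[t, j] * r[t]
        thr = lam * cj[j]
        if g > thr:
            wj = (g - thr) / a[j]
        elif g < -thr:
            wj = (g + thr) / a[j]
        else:
            wj = 0.0
        d = wj - w_new[j]
        if d != 0.0:
            for t in range(n):
                r[t] -= d * X[t, j]
            w_new[j] = wj
            gain += a[j] * d * d
    return gain


@njit(cache=True)
def _newton_cd(X, y, cj, lam, w, b, max_iter, tol, obj_path):
    """Proximal Newton with cyclical coordinate descent.

    Returns (b, n_iter, converged, capped).  ``w`` is updated in place and
    ``obj_path[:n_iter]`` holds the penalized objective after each outer
    iteration.
    """
    n = X.shape[0]
    p = X.shape[1]
    eta = np.empty(n)
    mu = np.empty(n)
    wt = np.empty(n)
    r = np.empty(n)
    a = np.empty(p)
    w_new = np.empty(p)
    w_try = np.empty(p)
    active = np.empty(p, dtype=np.bool_)
    capped = False
    obj = _penalized_objective(X, y, w, b, cj, lam)
    n_iter = 0
    converged = False
    for it in range(max_iter):
        # quadratic approximation at the current point
        for t in range(n):
            e = b
            for j in range(p):
                e += X[t, j] * w[j]
            if e > MAX_LINPRED:
                e = MAX_LINPRED
                capped = True
            eta[t] = e
            m = np.exp(e)
            mu[t] = m
            wt[t] = m if m > 1e-8 else 1e-8
            # working residual z - eta where z = eta + (y - mu)/wt
            r[t] = (y[t] - m) / wt[t]
        sw = 0.0
        for t in range(n):
            sw += wt[t]
        for j in range(p):
            s = 0.0
            for t in range(n):
                s += wt[t] * X[t, j] * X[t, j]
            a[j] = s
        for j in range(p):
            w_new[j] = w[j]
        b_new = b
        # inner coordinate descent on the penalized weighted LS problem:
        # full KKT passes alternate with passes over the active set only;
        # sweeps stop once their quadratic gain is negligible relative to
        # the outer objective tolerance
        inner_tol = 0.01 * tol * (abs(obj) + 1.0)
        for _round in range(100):
            gain = _cd_pass(X, r, wt, a, cj, lam, w_new, active, False, n, p)
            db = _intercept_step(r, wt, sw, n)
            b_new += db
            gain += sw * db * db
            if gain < inner_tol:
                break
            for j in range(p):
                active[j] = w_new[j] != 0.0
            for _sweep in range(1000):
                gain = _cd_pass(
                    X, r, wt, a, cj, lam, w_new, active, True, n, p
                )
                db = _intercept_step(r, wt, sw, n)
                b_new += db
                gain += sw * db * db
                if gain < inner_tol:
                    break
        # step halving keeps the true penalized objective non-decreasing
        step = 1.0
        obj_new = obj
        bt = b
        for _h in range(40):
            bt = b + step * (b_new - b)
            for j in range(p):
                w_try[j] = w[j] + step * (w_new[j] - w[j])
            obj_new = _penalized_objective(X, y, w_try, bt, cj, lam)
            if obj_new >= obj - 1e-12:
                break
            step *= 0.5
        b = bt
        for j in range(p):
            w[j] = w_try[j]
        obj_path[it] = obj_new
        n_iter = it + 1
        if abs(obj_new - obj) <= tol * (abs(obj) + 1e-10):
            obj = obj_new
            converged = True
            break
        obj = obj_new
    return b, n_iter, converged, capped


def _irls(X, y, w, b, max_iter, tol):
    """Iteratively reweighted least squares for the unpenalized model.

    Newton steps on the exact Poisson log-likelihood with step halving, so
    the objective path is non-decreasing like the coordinate-descent path.
    """
    n, p = X.shape
    A = np.column_stack([np.ones(n), X])
    theta = np.concatenate([[b], w])
    obj_path = []
    capped = False
    converged = False

    def objective(th):
        eta = np.minimum(A @ th, MAX_LINPRED)
        return float(np.sum(y * eta - np.exp(eta))), bool(np.any(A @ th > MAX_LINPRED))

    obj, _ = objective(theta)
    for _ in range(max_iter):
        eta = A @ theta
        cap = eta > MAX_LINPRED
        if np.any(cap):
            capped = True
            eta = np.minimum(eta, MAX_LINPRED)
        mu = np.exp(eta)
        grad = A.T @ (y - mu)
        hess = A.T @ (A * mu[:, None])
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        t = 1.0
        for _h in range(40):
            cand = theta + t * step
            obj_new, cap_new = objective(cand)
            if obj_new >= obj - 1e-12:
                break
            t *= 0.5
        theta = cand
        capped = capped or cap_new
        obj_path.append(obj_new)
        if abs(obj_new - obj) <= tol * (abs(obj) + 1e-10):
            converged = True
            obj = obj_new
            break
        obj = obj_new
    return theta[1:], float(theta[0]), np.array(obj_path), converged, capped


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------


def poisson_log_likelihood(y: np.ndarray, rate: np.ndarray) -> float:
    """Total Poisson log-likelihood sum_t [y_t log(rate_t) - rate_t - log y_t!].

    Rates are floored at 1e-12 (a zero rate with an observed spike would
    give -inf) with a warning.
    """
    y = np.asarray(y, dtype=float)
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 1e-12):
        warnings.warn("rate floored at 1e-12 in log-likelihood", RuntimeWarning)
        rate = np.maximum(rate, 1e-12)
    return float(np.sum(y * np.log(rate) - rate - gammaln(y + 1.0)))


class PoissonGLM(BaseEstimator):
    """Poisson regression with an exponential link and weighted L1 penalty.

    Maximizes ``sum_t [y_t eta_t - exp(eta_t)] - alpha * sum_j c_j |w_j|``
    with ``eta = intercept + X w``; the per-feature factors ``c_j`` allow
    some columns (e.g. cosine tuning terms) to stay unpenalized while
    others (coupling counts) carry the full penalty.

    Parameters
    ----------
    alpha : float
        Overall L1 penalty (lambda >= 0); 0 gives maximum likelihood.
    penalty_weights : array-like of shape (n_features,), optional
        Per-feature penalty factors c_j >= 0; default all ones.
    max_iter : int
        Outer proximal-Newton iteration cap.
    tol : float
        Relative change in penalized objective declaring convergence.
    warm_start : bool
        Reuse ``coef_``/``intercept_`` from a previous fit as the start.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Fitted weights; L1 soft-thresholding produces exact zeros.
    intercept_ : float
        Fitted log-rate baseline.
    objective_path_ : ndarray
        Penalized objective after each outer iteration (non-decreasing).
    n_iter_ : int
    """

    def __init__(
        self,
        alpha: float = 0.0,
        penalty_weights=None,
        max_iter: int = 1000,
        tol: float = 1e-8,
        warm_start: bool = False,
    ):
        self.alpha = alpha
        self.penalty_weights = penalty_weights
        self.max_iter = max_iter
        self.tol = tol
        self.warm_start = warm_start

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        if np.any(y < 0):
            raise ValueError("counts must be nonnegative")
        if not np.all(np.isfinite(X)):
            raise ValueError("design matrix contains non-finite values")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        n, p = X.shape
        cj = (
            np.ones(p)
            if self.penalty_weights is None
            else np.asarray(self.penalty_weights, dtype=np.float64)
        )
        if cj.shape != (p,):
            raise ValueError("penalty_weights must match n_features")
        if self.warm_start and hasattr(self, "coef_") and self.coef_.shape == (p,):
            w = self.coef_.copy()
            b = float(self.intercept_)
        else:
            w = np.zeros(p)
            b = float(np.log(max(y.mean(), 1e-3)))
        if self.alpha == 0.0 or not np.any(cj > 0):
            # no L1 term: plain IRLS (Newton steps via normal equations),
            # which is robust to correlated designs where cyclical CD crawls
            w, b, obj_path_full, converged, capped = _irls(
                X, y, w, b, self.max_iter, self.tol
            )
            n_iter = len(obj_path_full)
            obj_path = obj_path_full
        else:
            Xf = np.asfortranarray(X)
            obj_path = np.empty(self.max_iter)
            b, n_iter, converged, capped = _newton_cd(
                Xf, y, cj, float(self.alpha), w, b, self.max_iter, self.tol,
                obj_path,
            )
        if capped:
            warnings.warn(
                "linear predictor capped at %.0f (possible separation); "
                "weights are not MLEs" % MAX_LINPRED,
                RuntimeWarning,
            )
        if not converged and not capped:
            raise ConvergenceError(
                f"Poisson GLM did not converge in {self.max_iter} iterations "
                f"(final objective {obj_path[n_iter - 1]:.6g}, "
                f"last change {abs(obj_path[n_iter - 1] - obj_path[n_iter - 2]):.3g})"
            )
        self.coef_ = w
        self.intercept_ = b
        self.n_iter_ = int(n_iter)
        self.objective_path_ = obj_path[:n_iter].copy()
        self.n_features_in_ = p
        return self

    def linear_predictor(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.minimum(self.intercept_ + X @ self.coef_, MAX_LINPRED)

    def predict(self, X) -> np.ndarray:
        """Expected count per trial (the Poisson rate per bin)."""
        return np.exp(self.linear_predictor(X))

    def score(self, X, y) -> float:
        """Mean Poisson log-likelihood per trial."""
        return poisson_log_likelihood(y, self.predict(X)) / len(np.asarray(y))


# ---------------------------------------------------------------------------
# Design matrices and model fits
# ---------------------------------------------------------------------------


@dataclass
class DesignMatrix:
    """Per-neuron design: a tuning block and a coupling block.

    The coupling block holds the same-bin counts of the *other* neurons in
    the modelled subset; the target neuron's own counts are always
    excluded.
    """

    tuning_block: np.ndarray
    coupling_block: np.ndarray
    coupling_sources: np.ndarray  # neuron index of each coupling column
    target: int | None = None

    def __post_init__(self) -> None:
        self.tuning_block = np.atleast_2d(np.asarray(self.tuning_block, dtype=float))
        self.coupling_block = np.atleast_2d(
            np.asarray(self.coupling_block, dtype=float)
        )
        self.coupling_sources = np.asarray(self.coupling_sources, dtype=int)
        if self.target is not None and self.target in self.coupling_sources:
            raise ValueError(
                f"target neuron {self.target} appears in its own coupling block"
            )

    @property
    def n_trials(self) -> int:
        return self.tuning_block.shape[0]

    def blocks_for(self, variant: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(X, tuning column mask, coupling column mask) for a variant."""
        if variant == "tuning":
            X = self.tuning_block
            tmask = np.ones(X.shape[1], dtype=bool)
            cmask = np.zeros(X.shape[1], dtype=bool)
        elif variant == "coupling":
            X = self.coupling_block
            tmask = np.zeros(X.shape[1], dtype=bool)
            cmask = np.ones(X.shape[1], dtype=bool)
        elif variant == "full":
            X = np.hstack([self.tuning_block, self.coupling_block])
            tmask = np.zeros(X.shape[1], dtype=bool)
            tmask[: self.tuning_block.shape[1]] = True
            cmask = ~tmask
        else:
            raise ValueError(f"unknown variant {variant!r}; expected {VARIANTS}")
        return X, tmask, cmask


def build_design(
    counts: SpikeCounts,
    covariates: CovariateTable | None,
    basis_spec: BasisSpec | None,
    target: int,
    subset: np.ndarray | None = None,
    standardize: bool = False,
) -> DesignMatrix:
    """Assemble the design for one target neuron.

    ``subset`` restricts the coupling block to those neuron indices (the
    target is dropped from it automatically).  Coupling covariates stay on
    the raw count scale by default, so the L1 penalty acts on raw coupling
    coefficients; ``standardize=True`` z-scores them instead
    (zero-variance columns are left at zero).
    """
    n_trials = counts.n_trials
    if basis_spec is not None and covariates is not None:
        tuning = build_basis(covariates, basis_spec)
    else:
        tuning = np.empty((n_trials, 0))
    if subset is None:
        subset = np.arange(counts.n_neurons)
    subset = np.asarray(subset, dtype=int)
    sources = subset[subset != target]
    coupling = counts.counts[:, sources].astype(float)
    if standardize and coupling.size:
        sd = coupling.std(axis=0)
        coupling = (coupling - coupling.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    return DesignMatrix(tuning, coupling, sources, target=target)


@dataclass
class ModelFit:
    """A fitted LNP variant for one neuron."""

    variant: str
    baseline: float
    tuning_weights: np.ndarray | None
    coupling_weights: np.ndarray | None
    coupling_sources: np.ndarray | None
    penalty: float
    tc_penalty_fraction: float
    neuron: int | None = None
    cv_loglik: float | None = None
    basis_spec: BasisSpec | None = None
    extras: dict = field(default_factory=dict)

    def rates(self, design: DesignMatrix) -> np.ndarray:
        """Predicted rate per bin on a design matrix."""
        eta = self.linear_predictor(design)
        return np.exp(eta)

    def linear_predictor(self, design: DesignMatrix) -> np.ndarray:
        eta = np.full(design.n_trials, self.baseline)
        if self.tuning_weights is not None:
            eta = eta + design.tuning_block @ self.tuning_weights
        if self.coupling_weights is not None:
            eta = eta + design.coupling_block @ self.coupling_weights
        return np.minimum(eta, MAX_LINPRED)


def _penalty_factors(
    tmask: np.ndarray, cmask: np.ndarray, basis_spec: BasisSpec | None,
    tc_penalty_fraction: float | None,
) -> tuple[np.ndarray, float]:
    """Per-column penalty factors: coupling 1, tuning 0 or a small fraction.

    RBF expansions (place/tonotopic bases) get ``tc_penalty_fraction`` of
    the coupling penalty by default (0.2); low-dimensional cosine bases are
    unpenalized.
    """
    if tc_penalty_fraction is None:
        rbf = basis_spec is not None and basis_spec.kind.startswith("rbf")
        tc_penalty_fraction = 0.2 if rbf else 0.0
    cj = np.zeros(tmask.size)
    cj[cmask] = 1.0
    cj[tmask] = tc_penalty_fraction
    return cj, tc_penalty_fraction


def fit_glm(
    counts_for_neuron: np.ndarray,
    design: DesignMatrix,
    variant: str = "full",
    penalty: float = 0.0,
    tc_penalty_fraction: float | None = None,
    basis_spec: BasisSpec | None = None,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> ModelFit:
    """Fit one LNP variant for one neuron (ML at penalty 0, MAP otherwise)."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    y = np.asarray(counts_for_neuron, dtype=float)
    X, tmask, cmask = design.blocks_for(variant)
    cj, tcf = _penalty_factors(tmask, cmask, basis_spec, tc_penalty_fraction)
    est = PoissonGLM(alpha=penalty, penalty_weights=cj, max_iter=max_iter, tol=tol)
    est.fit(X, y)
    return ModelFit(
        variant=variant,
        baseline=float(est.intercept_),
        tuning_weights=est.coef_[tmask].copy() if tmask.any() or variant != "coupling" else None,
        coupling_weights=est.coef_[cmask].copy() if variant != "tuning" else None,
        coupling_sources=design.coupling_sources.copy() if variant != "tuning" else None,
        penalty=float(penalty),
        tc_penalty_fraction=tcf,
        neuron=design.target,
        basis_spec=basis_spec,
    )


def penalty_path(
    counts_for_neuron: np.ndarray,
    design: DesignMatrix,
    variant: str,
    n_points: int = 30,
    decades: float = 4.0,
    tc_penalty_fraction: float | None = None,
    basis_spec: BasisSpec | None = None,
) -> np.ndarray:
    """Log-spaced penalty grid from lambda_max down ``decades`` decades.

    lambda_max is the smallest penalty at which every penalized weight is
    exactly zero, computed from the score of the null fit (intercept plus
    any unpenalized columns).
    """
    y = np.asarray(counts_for_neuron, dtype=float)
    X, tmask, cmask = design.blocks_for(variant)
    cj, _ = _penalty_factors(tmask, cmask, basis_spec, tc_penalty_fraction)
    pen = cj > 0
    if not pen.any():
        return np.array([0.0])
    # null fit: only unpenalized columns active
    free = ~pen
    est = PoissonGLM(alpha=0.0)
    est.fit(X[:, free], y)
    mu = est.predict(X[:, free])
    grad = X[:, pen].T @ (y - mu)
    lam_max = float(np.max(np.abs(grad) / cj[pen]))
    # small multiplicative guard: the gradient bound is exact only when the
    # unpenalized block is held at the null fit, and the boundary case is
    # numerically fragile
    lam_max = max(lam_max, 1e-6) * 1.02
    return np.geomspace(lam_max, lam_max * 10.0 ** (-decades), n_points)


def cv_folds(n_trials: int, n_folds: int, seed: int):
    """Trial-wise CV folds, a pure function of (n_trials, n_folds, seed).

    The same fold assignment is therefore shared across the three model
    variants for a given dataset, which makes paired accuracy comparisons
    valid.
    """
    if n_trials < n_folds:
        raise ValueError(f"need at least {n_folds} trials for {n_folds}-fold CV")
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**31))
    return list(kf.split(np.arange(n_trials)))


def select_penalty(
    counts_for_neuron: np.ndarray,
    design: DesignMatrix,
    variant: str,
    penalty_grid: np.ndarray | None = None,
    n_folds: int = 10,
    seed: int = 0,
    tc_penalty_fraction: float | None = None,
    basis_spec: BasisSpec | None = None,
    rule: str = "1se",
) -> tuple[float, np.ndarray]:
    """Choose the L1 penalty by 10-fold cross-validated log-likelihood.

    Returns ``(penalty, cv_loglik_per_grid_point)`` where the CV
    log-likelihood is the mean held-out Poisson log-likelihood per trial.
    Fits along the path are warm-started from the previous (larger)
    penalty, glmnet-style.

    ``rule='1se'`` (default, the glmnet convention) picks the largest
    penalty whose CV log-likelihood is within one standard error (over
    folds) of the maximum; under a null coupling design the near-flat CV
    curve then resolves to the sparse end instead of a noise-favoured
    small penalty.  ``rule='max'`` picks the plain argmax.
    """
    y = np.asarray(counts_for_neuron, dtype=float)
    if penalty_grid is None:
        penalty_grid = penalty_path(
            y, design, variant,
            tc_penalty_fraction=tc_penalty_fraction, basis_spec=basis_spec,
        )
    penalty_grid = np.asarray(penalty_grid, dtype=float)
    if penalty_grid.size == 0:
        raise ValueError("penalty_grid must be nonempty")
    if np.any(penalty_grid < 0):
        raise ValueError("penalties must be nonnegative")
    if rule not in ("1se", "max"):
        raise ValueError("rule must be '1se' or 'max'")
    order = np.argsort(penalty_grid)[::-1]  # largest first for warm starts
    X, tmask, cmask = design.blocks_for(variant)
    cj, _ = _penalty_factors(tmask, cmask, basis_spec, tc_penalty_fraction)
    folds = cv_folds(len(y), n_folds, seed)
    fold_ll = np.zeros((len(folds), penalty_grid.size))
    for f, (train, test) in enumerate(folds):
        est = PoissonGLM(penalty_weights=cj, warm_start=True)
        for k in order:
            est.set_params(alpha=float(penalty_grid[k]))
            est.fit(X[train], y[train])
            fold_ll[f, k] = poisson_log_likelihood(
                y[test], est.predict(X[test])
            ) / len(test)
    cv_ll = fold_ll.mean(axis=0)
    best = int(np.argmax(cv_ll))
    if rule == "1se" and penalty_grid.size > 1:
        se = fold_ll[:, best].std(ddof=1) / np.sqrt(len(folds))
        ok = cv_ll >= cv_ll[best] - se
        chosen = int(np.flatnonzero(ok)[np.argmax(penalty_grid[ok])])
    else:
        chosen = best
    return float(penalty_grid[chosen]), cv_ll


def fit_population(
    data: SpikeCounts,
    covariates: CovariateTable | None,
    basis_spec: BasisSpec | None,
    variant: str = "full",
    subset: np.ndarray | None = None,
    seed: int = 0,
    penalty: float | str = "cv",
    penalty_grid: np.ndarray | None = None,
    n_folds: int = 10,
    tc_penalty_fraction: float | None = None,
) -> list[ModelFit]:
    """Fit one model variant for every neuron in ``subset``.

    ``penalty='cv'`` selects the L1 penalty per neuron by cross-validation;
    a float fixes it.  Per-neuron failures are caught, reported at the end,
    and the remaining neurons are still fit; failed entries are ``None``.
    """
    if subset is None:
        subset = np.arange(data.n_neurons)
    subset = np.asarray(subset, dtype=int)
    fits: list[ModelFit | None] = []
    failures: list[tuple[int, Exception]] = []
    for target in subset:
        try:
            design = build_design(data, covariates, basis_spec, int(target), subset)
            y = data.counts[:, target]
            if penalty == "cv" and design.blocks_for(variant)[2].any():
                grid = (
                    penalty_grid
                    if penalty_grid is not None
                    else penalty_path(
                        y, design, variant,
                        tc_penalty_fraction=tc_penalty_fraction,
                        basis_spec=basis_spec,
                    )
                )
                lam, cv_ll = select_penalty(
                    y, design, variant, grid, n_folds, seed,
                    tc_penalty_fraction, basis_spec,
                )
                cv_best = float(cv_ll[np.argmin(np.abs(np.asarray(grid) - lam))])
            else:
                lam = 0.0 if penalty == "cv" else float(penalty)
                cv_best = None
            fit = fit_glm(
                y, design, variant, lam, tc_penalty_fraction, basis_spec
            )
            fit.cv_loglik = cv_best
            fits.append(fit)
        except Exception as exc:  # propagate per neuron, continue others
            failures.append((int(target), exc))
            fits.append(None)
    if failures:
        msg = "; ".join(f"neuron {i}: {e}" for i, e in failures[:5])
        warnings.warn(
            f"{len(failures)}/{len(subset)} fits failed ({msg})", RuntimeWarning
        )
    return fits
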