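"""Independent oracles used only by the tests.

These deliberately avoid the package's own solver paths: a dense Newton
maximizer of the exact Poisson likelihood, a Gauss-Hermite quadrature of
the copula cross-moment, and exact enumeration of small truncated coupled
joints (for symmetric coupling the joint is a closed-form Gibbs measure;
power iteration of the sweep kernel provides a second route).
"""

import itertools

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import norm, poisson
from scipy.special import roots_hermitenorm


def newton_poisson_ml(X, y, max_iter=200, tol=1e-12):
    """Dense Newton maximization of the exact Poisson log-likelihood with
    intercept; independent of the package solver."""
    X = np.column_stack([np.ones(len(y)), np.asarray(X, dtype=float)])
    y = np.asarray(y, dtype=float)
    w = np.zeros(X.shape[1])
    w[0] = np.log(max(y.mean(), 1e-3))
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = X @ w
        mu = np.exp(eta)
        grad = X.T @ (y - mu)
        hess = X.T @ (X * mu[:, None])
        step = np.linalg.solve(hess, grad)
        t = 1.0
        ll = np.sum(y * eta - mu)
        while True:
            w_new = w + t * step
            ll_new = np.sum(y * (X @ w_new) - np.exp(X @ w_new))
            if ll_new >= ll or t < 1e-12:
                break
            t /= 2
        w = w_new
        if abs(ll_new - ll_old) < tol * (abs(ll_new) + 1):
            break
        ll_old = ll_new
    return w  # [intercept, coefs...]


def poisson_loglik(y, rate):
    y = np.asarray(y, dtype=float)
    rate = np.maximum(np.asarray(rate, dtype=float), 1e-12)
    return float(np.sum(y * np.log(rate) - rate - gammaln(y + 1)))


def _poisson_latent_edges(mean, kmax):
    """Latent thresholds: count k corresponds to z in (edges[k], edges[k+1]]."""
    cdf = np.clip(poisson.cdf(np.arange(-1, kmax + 1), mean), 1e-16, 1 - 1e-16)
    return norm.ppf(cdf)


def gh_count_correlation(r, mean, kmax=60):
    """Quadrature oracle for the copula count correlation.

    The inner expectation E[g(Z2) | Z1 = z] is the analytic tail sum
    sum_k Phi_bar((z_k - r z)/s); the outer integral over z is done by
    numerical quadrature per latent cell, avoiding the step discontinuity.
    """
    from scipy.integrate import quad

    edges = _poisson_latent_edges(mean, kmax)
    s = np.sqrt(1.0 - r * r)
    zk = edges[1:]  # thresholds for counts >= 1

    def inner(z):
        return norm.pdf(z) * np.sum(norm.sf((zk - r * z) / s))

    exy = 0.0
    for k in range(1, kmax + 1):  # E[XY] = sum_k E[1(Z1 > z_k) g(Z2)]
        lo = edges[k]
        if lo > 9:
            break
        val, _ = quad(inner, lo, 9.0, limit=200)
        exy += val
    return (exy - mean * mean) / mean


def copula_pair_pmf(rho, mean, latent_r, kmax=10):
    """Joint PMF of a correlated Poisson pair on {0..kmax}^2.

    P(X=k, Y=l) integrated per latent rectangle: outer 1-D quadrature over
    z1 with the analytic conditional normal CDF over z2."""
    from scipy.integrate import quad

    edges = _poisson_latent_edges(mean, kmax)
    s = np.sqrt(1 - latent_r**2)
    pmf = np.zeros((kmax + 1, kmax + 1))
    for k in range(kmax + 1):
        a, b = edges[k], edges[k + 1]
        for l in range(kmax + 1):
            c, d = edges[l], edges[l + 1]

            def f(z):
                return norm.pdf(z) * (
                    norm.cdf((d - latent_r * z) / s)
                    - norm.cdf((c - latent_r * z) / s)
                )

            pmf[k, l], _ = quad(f, max(a, -9), min(b, 9), limit=100)
    return pmf


def symmetric_joint_pmf(eta, beta, max_count):
    """Exact truncated joint for symmetric coupling: the Gibbs measure
    p(y) ∝ prod_i exp(eta_i y_i)/y_i! * exp(sum_{i<j} beta_ij y_i y_j)."""
    eta = np.asarray(eta, dtype=float)
    beta = np.asarray(beta, dtype=float)
    assert np.allclose(beta, beta.T), "oracle requires symmetric coupling"
    n = len(eta)
    grid = np.arange(max_count + 1)
    shape = (max_count + 1,) * n
    logp = np.zeros(shape)
    for i in range(n):
        sl = [None] * n
        sl[i] = slice(None)
        yi = grid[tuple(sl)]
        logp = logp + eta[i] * yi - gammaln(yi + 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            sli = [None] * n
            sli[i] = slice(None)
            slj = [None] * n
            slj[j] = slice(None)
            logp = logp + beta[i, j] * grid[tuple(sli)] * grid[tuple(slj)]
    return np.exp(logp - logsumexp(logp))


def gibbs_sweep_stationary(eta, beta, max_count, n_iter=2000, tol=1e-12):
    """Stationary distribution of the random-permutation Gibbs sweep kernel
    by power iteration (averaging over all update orders)."""
    eta = np.asarray(eta, dtype=float)
    n = len(eta)
    m = max_count + 1
    states = np.array(list(itertools.product(range(m), repeat=n)))
    p = np.full(len(states), 1.0 / len(states))
    grid = np.arange(m)

    index_of = {tuple(s): k for k, s in enumerate(states)}

    def apply_site(p, i):
        out = np.zeros_like(p)
        # P(y_i = k | rest): truncated Poisson at the conditional rate
        # (beta has zero diagonal, so states @ beta[i] drops y_i itself)
        rate = np.exp(np.minimum(eta[i] + states @ beta[i], 30.0))
        lp = grid[None, :] * np.log(rate)[:, None] - rate[:, None] - gammaln(grid + 1)[None, :]
        lp -= logsumexp(lp, axis=1, keepdims=True)
        cond = np.exp(lp)
        for s_idx in range(len(states)):
            if p[s_idx] == 0:
                continue
            base = states[s_idx].copy()
            for k in range(m):
                base[i] = k
                out[index_of[tuple(base)]] += p[s_idx] * cond[s_idx, k]
        return out

    orders = list(itertools.permutations(range(n)))
    for _ in range(n_iter):
        new = np.zeros_like(p)
        for order in orders:
            q = p
            for i in order:
                q = apply_site(q, i)
            new += q / len(orders)
        if np.abs(new - p).sum() < tol:
            p = new
            break
        p = new
    return states, p
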