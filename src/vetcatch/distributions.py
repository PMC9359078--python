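"""Count-distribution log-pmfs and the intrinsic CAR log-density.

All pmfs are vectorized over numpy arrays and computed in log space. The
negative binomial uses the mean/shape parameterization
(variance mu + mu^2/shape); the Conway-Maxwell-Poisson normalizer is a
truncated series, with a bisection wrapper that solves for the rate lambda
giving a requested mean so that mu = e * R holds across families.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, logsumexp

_CMP_TOL = 1e-12
_CMP_JMAX = 100_000


def nb_logpmf(y, mu, shape):
    """log NB(y; mean=mu, shape=phi) with Var = mu + mu^2/phi."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    shape = np.asarray(shape, dtype=float)
    if np.any(mu <= 0) or np.any(shape <= 0):
        raise ValueError("mu and shape must be > 0")
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("y must be a nonnegative integer")
    return (
        gammaln(y + shape)
        - gammaln(shape)
        - gammaln(y + 1)
        + shape * (np.log(shape) - np.log(shape + mu))
        + y * (np.log(mu) - np.log(shape + mu))
    )


def poisson_logpmf(y, mu):
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return y * np.log(mu) - mu - gammaln(y + 1)


def zi_logpmf(y, base_logpmf_at_y, base_logpmf_at_0, pi):
    """Zero-inflated log-pmf from the base log-pmf, stably in log space.

    y = 0 -> log(pi + (1-pi) f(0));  y > 0 -> log(1-pi) + log f(y).
    """
    y = np.asarray(y)
    pi = np.asarray(pi, dtype=float)
    if np.any(pi < 0) or np.any(pi > 1):
        raise ValueError("pi must be in [0, 1]")
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi)
        log1m_pi = np.log1p(-pi)
    at_zero = np.logaddexp(log_pi, log1m_pi + base_logpmf_at_0)
    positive = log1m_pi + np.asarray(base_logpmf_at_y, dtype=float)
    return np.where(y == 0, at_zero, positive)


def cmp_lognorm(log_lambda, nu_cmp):
    """log Z(lambda, nu) = log sum_j lambda^j / (j!)^nu, truncated.

    Terms are accumulated until the next term falls below 1e-12 of the
    running sum (or j hits 1e5, an error for practical purposes).
    """
    log_lambda = np.asarray(log_lambda, dtype=float)
    nu = float(nu_cmp)
    if nu <= 0:
        raise ValueError("nu_cmp must be > 0")
    # term_j in log space: j*log(lambda) - nu*gammaln(j+1)
    out = np.zeros_like(log_lambda)  # j=0 term is 1 -> log term 0
    flat = np.atleast_1d(log_lambda)
    res = np.empty_like(flat)
    for idx, ll in np.ndenumerate(flat):
        total = 0.0  # log of running sum, starts at log(1)
        j = 0
        while True:
            j += 1
            term = j * ll - nu * gammaln(j + 1)
            new_total = np.logaddexp(total, term)
            if term - new_total < np.log(_CMP_TOL):
                total = new_total
                break
            total = new_total
            if j >= _CMP_JMAX:
                raise ValueError("CMP normalizer did not converge (nu too small?)")
        res[idx] = total
    out = res.reshape(np.shape(log_lambda)) if np.shape(log_lambda) else float(res[0])
    return out


def cmp_logpmf(y, lam, nu_cmp):
    """log CMP(y; lambda, nu) = y log lambda - nu log y! - log Z."""
    y = np.asarray(y, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("lambda must be > 0")
    log_lam = np.log(lam)
    return y * log_lam - nu_cmp * gammaln(y + 1) - cmp_lognorm(log_lam, nu_cmp)


def cmp_mean(lam, nu_cmp, jmax=500):
    """Mean of CMP by direct (truncated) series evaluation."""
    lam = np.asarray(lam, dtype=float)
    j = np.arange(jmax + 1, dtype=float)
    logterms = j[None, :] * np.log(lam)[..., None] - nu_cmp * gammaln(j + 1)[None, :]
    logZ = logsumexp(logterms, axis=-1)
    with np.errstate(divide="ignore"):
        logEy = logsumexp(logterms[..., 1:] + np.log(j[1:]), axis=-1)
    return np.exp(logEy - logZ)


def cmp_lambda_for_mean(mu, nu_cmp, tol=1e-8, maxiter=200):
    """Solve for lambda such that the CMP mean equals mu, by bisection.

    Vectorized over mu; uses the approximation lambda ~ mu^nu to bracket.
    """
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    if np.any(mu <= 0):
        raise ValueError("target mean must be > 0")
    lo = np.full_like(mu, 1e-12)
    hi = np.maximum(mu**nu_cmp, 1.0) * 4.0 + 1.0
    # expand hi until the mean exceeds the target everywhere
    for _ in range(60):
        short = cmp_mean(hi, nu_cmp) < mu
        if not short.any():
            break
        hi[short] *= 2.0
    for _ in range(maxiter):
        mid = 0.5 * (lo + hi)
        too_low = cmp_mean(mid, nu_cmp) < mu
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
        if np.max(hi - lo) < tol:
            break
    return 0.5 * (lo + hi)


def car_quadform(nu, edges):
    """sum over edges (i,j) of (nu_i - nu_j)^2."""
    nu = np.asarray(nu, dtype=float)
    if len(edges) == 0:
        return 0.0
    e = np.asarray(edges, dtype=int)
    d = nu[e[:, 0]] - nu[e[:, 1]]
    return float(d @ d)


def car_logdensity(nu, edges, tau, n_components=None, n=None):
    """Improper intrinsic-CAR log-density (up to an additive constant).

    ((n - c)/2) log tau - (tau/2) * sum_edges (nu_i - nu_j)^2, where c is the
    number of connected components of the graph. The density is improper: it
    is invariant to adding a constant within each component, which is why a
    sum-to-zero constraint accompanies it. The implied full conditional of
    nu_i is Normal(mean of its neighbors, 1/(m_i * tau)).
    """
    nu = np.asarray(nu, dtype=float)
    if tau <= 0:
        raise ValueError("tau must be > 0")
    n = len(nu) if n is None else n
    if n_components is None:
        n_components = _count_components(n, edges)
    q = car_quadform(nu, edges)
    return 0.5 * (n - n_components) * np.log(tau) - 0.5 * tau * q


def _count_components(n, edges):
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    return len({find(i) for i in range(n)})
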