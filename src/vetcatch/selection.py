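"""Approximate leave-one-out cross-validation (PSIS-LOO) and model ranking.

Candidate models are compared by the expected log pointwise predictive
density (ELPD) estimated from the posterior log-likelihood matrix with
Pareto-smoothed importance sampling: for each observation the largest raw
importance ratios are replaced by expected order statistics of a fitted
generalized Pareto distribution and capped at the raw maximum. Higher ELPD
is better; the tail-shape diagnostic k flags observations whose
importance-sampling estimate is unreliable (k > 0.7 conventionally).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .spatial_model import ModelSpec, PosteriorDraws, pointwise_loglik_arrays


@dataclass
class LooResult:
    elpd_loo: float
    se: float
    pointwise: np.ndarray  # elpd_i
    pareto_k: np.ndarray

    @property
    def n_bad_k(self) -> int:
        return int(np.sum(self.pareto_k > 0.7))


def pointwise_loglik(
    draws: PosteriorDraws, counts: pd.DataFrame, spec: ModelSpec, thin: int = 1
) -> np.ndarray:
    """S x N matrix of per-draw, per-observation log-likelihoods.

    Observations follow the (tract_id, species, period)-sorted order of the
    stratified grid, matching ``draws.obs_index``.
    """
    counts = counts.sort_values(["tract_id", "species", "period"]).reset_index(drop=True)
    y = counts[f"y_{spec.outcome}"].to_numpy(float)
    e = counts[f"e_{spec.outcome}"].to_numpy(float)
    from .spatial_model import build_design

    X, cols = build_design(counts, spec.fixed_effects)
    if cols != draws.design_columns:
        raise ValueError("design mismatch between draws and counts")
    tindex = {t: i for i, t in enumerate(draws.tract_ids)}
    try:
        tr = counts["tract_id"].map(tindex).to_numpy()
        if np.any(pd.isna(tr)):
            raise KeyError
        tr = tr.astype(int)
    except (KeyError, ValueError):
        raise ValueError("counts contain tracts unknown to the posterior draws")

    beta_c = draws.stacked("beta_count")[::thin]
    nu_c = draws.stacked("nu_count")[::thin]
    S = beta_c.shape[0]
    eta_c = beta_c @ X.T + nu_c[:, tr]
    if spec.zero_inflated:
        eta_z = draws.stacked("beta_zero")[::thin] @ X.T + draws.stacked("nu_zero")[::thin][:, tr]
    else:
        eta_z = np.zeros_like(eta_c)
    shape = draws.stacked("shape")[::thin] if spec.has_shape else [None] * S
    out = np.empty((S, len(y)))
    for s in range(S):
        out[s] = pointwise_loglik_arrays(y, e, eta_c[s], eta_z[s], spec, shape[s])
    return out


def _gpd_fit(x: np.ndarray):
    """Generalized-Pareto fit to exceedances by the Zhang-Stephens
    method-of-moments-plus-profile posterior; returns (k, sigma)."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    prior_bs, prior_k = 3.0, 10.0
    m = 30 + int(np.sqrt(n))
    b = 1.0 - np.sqrt(m / (np.arange(1, m + 1) - 0.5))
    b /= prior_bs * x[int(n / 4 + 0.5) - 1]
    b += 1.0 / x[-1]
    k = np.log1p(-b[:, None] * x).mean(axis=1)
    logl = n * (np.log(-b / k) - k - 1.0)
    w = 1.0 / np.exp(logl - logl[:, None]).sum(axis=1)
    good = w >= 10 * np.finfo(float).eps
    b, w = b[good], w[good]
    w /= w.sum()
    b_post = float(np.sum(b * w))
    k_post = float(np.log1p(-b_post * x).mean())
    sigma = -k_post / b_post
    k_post = (n * k_post + prior_k * 0.5) / (n + prior_k)
    return k_post, sigma


def _gpd_quantile(p, k, sigma):
    if abs(k) < 1e-12:
        return -sigma * np.log1p(-p)
    return sigma / k * (np.power(1.0 - p, -k) - 1.0)


def psis_smooth_weights(log_ratios: np.ndarray, tail_frac: float = 0.2):
    """Smooth one observation's log importance ratios; returns (log_w, k)."""
    lr = np.asarray(log_ratios, dtype=float)
    if not np.all(np.isfinite(lr)):
        raise ValueError("non-finite importance ratios")
    S = len(lr)
    lw = lr - lr.max()
    if np.allclose(lw, lw[0]):
        return lw, np.nan  # zero-variance weights: nothing to smooth
    M = int(np.ceil(min(tail_frac * S, 3.0 * np.sqrt(S))))
    if M < 5:
        return lw, np.nan
    order = np.argsort(lw)
    tail_idx = order[-M:]
    cutoff = lw[order[-M - 1]]
    exceed = np.exp(lw[tail_idx]) - np.exp(cutoff)
    if np.allclose(exceed, 0.0):
        return lw, np.nan
    k, sigma = _gpd_fit(exceed[exceed > 0] if np.any(exceed <= 0) else exceed)
    probs = (np.arange(1, M + 1) - 0.5) / M
    smoothed = np.log(
        _gpd_quantile(probs, k, sigma) + np.exp(cutoff)
    )
    ranks = np.empty(M, dtype=int)
    ranks[np.argsort(lw[tail_idx])] = np.arange(M)
    out = lw.copy()
    out[tail_idx] = np.minimum(smoothed[ranks], 0.0)  # cap at max raw weight (=0 shifted)
    return out, k


def psis_loo(loglik: np.ndarray) -> LooResult:
    """PSIS-LOO ELPD from an S x N pointwise log-likelihood matrix."""
    ll = np.asarray(loglik, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("need an S x N matrix with S >= 2 draws")
    S, N = ll.shape
    if S < 100:
        import warnings

        warnings.warn(f"only {S} draws: PSIS may be unstable below 100")
    elpd_i = np.empty(N)
    pareto_k = np.empty(N)
    for i in range(N):
        if not np.all(np.isfinite(ll[:, i])):
            raise ValueError(f"non-finite log-likelihood for observation {i}")
        lw, k = psis_smooth_weights(-ll[:, i])
        lw = lw - logsumexp(lw)
        elpd_i[i] = logsumexp(lw + ll[:, i])
        pareto_k[i] = k
    return LooResult(
        elpd_loo=float(elpd_i.sum()),
        se=float(np.sqrt(N * np.var(elpd_i))),
        pointwise=elpd_i,
        pareto_k=pareto_k,
    )


def compare(results: list[tuple[ModelSpec, LooResult]]) -> pd.DataFrame:
    """Rank models by elpd_loo; differences are pairwise-pointwise vs the best.

    All results must be computed on the same observations (equal N).
    """
    if not results:
        raise ValueError("no results to compare")
    n = len(results[0][1].pointwise)
    if any(len(r.pointwise) != n for _, r in results):
        raise ValueError("results computed on different observation sets")
    order = sorted(range(len(results)), key=lambda k: -results[k][1].elpd_loo)
    best = results[order[0]][1]
    rows = []
    for k in order:
        spec, res = results[k]
        diff_i = res.pointwise - best.pointwise
        rows.append(
            {
                "family": spec.family,
                "prior": spec.re_prior,
                "outcome": spec.outcome,
                "elpd_loo": res.elpd_loo,
                "se": res.se,
                "elpd_diff": float(diff_i.sum()),
                "se_diff": float(np.sqrt(n * np.var(diff_i))),
                "max_pareto_k": float(np.nanmax(res.pareto_k))
                if np.any(np.isfinite(res.pareto_k))
                else np.nan,
                "n_bad_k": res.n_bad_k,
            }
        )
    return pd.DataFrame(rows)
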