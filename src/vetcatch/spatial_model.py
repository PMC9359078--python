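"""Hierarchical Bayesian count models for tract-level registry counts.

The observation model per stratum (tract i, species/period covariates j) is

    Y_ij = 0                  with probability pi_ij        (zi families)
    Y_ij ~ F(mu_ij)           with probability 1 - pi_ij

    mu_ij = e_ij * R_ij
    log R_ij          = beta0 + beta_species + beta_period + nu_i
    logit pi_ij       = gamma0 + gamma_species + gamma_period + omega_i

with F one of Poisson, negative binomial (mean/shape) or mean-parameterized
Conway-Maxwell-Poisson, and tract effects nu (and omega for the zero part)
given either an exchangeable Normal(0, 1/tau) prior or an intrinsic CAR
prior with precision tau(D - W).

Fitting is by an adaptive Metropolis-within-Gibbs sampler written for this
model: fixed-effect blocks use adaptive random-walk proposals, tract effects
are updated site-by-site in graph-coloring batches (same-color tracts are
conditionally independent under the pairwise CAR factorization, so the
batch update is vectorized), and the precisions tau are conjugate Gibbs
draws. Intrinsic-CAR identifiability is handled the way established CAR
samplers do: effects are re-centred to component-wise zero mean at each
iteration. Isolated tracts get a proper Normal(0, 1/tau) prior.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from . import distributions as dist
from .region import TractGraph

log = logging.getLogger(__name__)

FAMILIES = ("poisson", "zip", "nb", "zinb", "cmp", "zicmp")
ZI_FAMILIES = ("zip", "zinb", "zicmp")
RE_PRIORS = ("exchangeable", "car")


@dataclass(frozen=True)
class ModelSpec:
    """Likelihood family, random-effect prior and outcome selection."""

    family: str = "zinb"
    re_prior: str = "car"
    outcome: str = "visits"  # selects y_<outcome> and e_<outcome> columns
    share_random_effect: bool = False
    fixed_effects: tuple[str, ...] = ("species", "period")

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.re_prior not in RE_PRIORS:
            raise ValueError(f"re_prior must be one of {RE_PRIORS}")

    @property
    def zero_inflated(self) -> bool:
        return self.family in ZI_FAMILIES

    @property
    def base_family(self) -> str:
        return {"zip": "poisson", "zinb": "nb", "zicmp": "cmp"}.get(
            self.family, self.family
        )

    @property
    def has_shape(self) -> bool:
        return self.base_family in ("nb", "cmp")


@dataclass(frozen=True)
class Priors:
    """Weakly-informative defaults for parameters the model block leaves open."""

    beta_sd: float = 5.0
    tau_shape: float = 1.0
    tau_rate: float = 0.01
    nb_shape_a: float = 0.01
    nb_shape_b: float = 0.01
    nb_shape_floor: float = 1e-4
    cmp_nu_logmean: float = 0.0
    cmp_nu_logsd: float = 1.0


@dataclass(frozen=True)
class McmcSettings:
    chains: int = 4
    iterations: int = 4000  # total per chain, warmup included
    warmup_frac: float = 0.25
    seed: int = 0
    thin: int = 1

    @property
    def warmup(self) -> int:
        return int(round(self.iterations * self.warmup_frac))


@dataclass
class PosteriorDraws:
    """Post-warmup draws keyed by parameter name.

    Scalar parameters have shape (chains, draws); vector tract effects
    (nu_count, nu_zero) have shape (chains, draws, n_tracts) with columns
    in ``tract_ids`` order. ``design_columns`` documents the fixed-effect
    coding (treatment contrasts, reference feline / first period).
    """

    params: dict[str, np.ndarray]
    tract_ids: list[str]
    design_columns: list[str]
    spec: ModelSpec
    mcmc: McmcSettings
    rhat_warning: bool = False
    obs_index: pd.DataFrame | None = None

    @property
    def n_draws(self) -> int:
        a = next(iter(self.params.values()))
        return a.shape[0] * a.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws with chains flattened: (chains*draws, ...)."""
        a = self.params[name]
        return a.reshape(-1, *a.shape[2:])

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for name, a in self.params.items():
            C, S = a.shape[:2]
            if a.ndim == 2:
                labels = [name]
                flat = a[:, :, None]
            else:
                labels = [f"{name}[{t}]" for t in (
                    self.tract_ids if name.startswith("nu") else self.design_columns
                )]
                flat = a
            for k, lab in enumerate(labels):
                for c in range(C):
                    rows.append(
                        pd.DataFrame(
                            {
                                "chain": c,
                                "iter": np.arange(S),
                                "parameter": lab,
                                "value": flat[c, :, k],
                            }
                        )
                    )
        return pd.concat(rows, ignore_index=True)

    def save(self, csv_path, json_path) -> None:
        self.to_long_frame().to_csv(csv_path, index=False)
        meta = {
            "spec": vars(self.spec) | {"fixed_effects": list(self.spec.fixed_effects)},
            "mcmc": vars(self.mcmc),
            "tract_ids": self.tract_ids,
            "design_columns": self.design_columns,
            "rhat_warning": self.rhat_warning,
        }
        with open(json_path, "w") as fh:
            json.dump(meta, fh)

    def to_arviz(self):
        import arviz as az

        data = {}
        for name, a in self.params.items():
            data[name] = a
        return az.from_dict(posterior=data)


# ---------------------------------------------------------------------------
# design and data preparation


def build_design(counts: pd.DataFrame, fixed_effects=("species", "period")):
    """Treatment-coded design matrix (intercept, canine, P2.., Pk).

    Levels with a single observed value are dropped (e.g. the period term in
    a single-period fit).
    """
    cols = {"intercept": np.ones(len(counts))}
    if "species" in fixed_effects and counts["species"].nunique() > 1:
        cols["species_canine"] = (counts["species"] == "canine").to_numpy(float)
    if "period" in fixed_effects and counts["period"].nunique() > 1:
        for label in sorted(counts["period"].unique())[1:]:
            cols[f"period_{label}"] = (counts["period"] == label).to_numpy(float)
    X = np.column_stack(list(cols.values()))
    return X, list(cols)


class _ModelData:
    """Preprocessed arrays for the sampler and likelihood evaluation."""

    def __init__(self, counts, spec: ModelSpec, graph: TractGraph | None):
        counts = counts.sort_values(["tract_id", "species", "period"]).reset_index(
            drop=True
        )
        ycol, ecol = f"y_{spec.outcome}", f"e_{spec.outcome}"
        for c in (ycol, ecol):
            if c not in counts:
                raise ValueError(f"counts missing column {c}")
        if np.any(counts[ecol] < 0):
            raise ValueError("expected counts must be >= 0")
        self.counts = counts
        self.y = counts[ycol].to_numpy(float)
        self.e = counts[ecol].to_numpy(float)
        self.active = self.e > 0  # e = 0 forces P(y=0) = 1
        if np.any(self.y[~self.active] > 0):
            raise ValueError("positive count in a stratum with zero expected count")
        self.X, self.design_columns = build_design(counts, spec.fixed_effects)
        self.tract_ids = sorted(counts["tract_id"].unique())
        tindex = {t: i for i, t in enumerate(self.tract_ids)}
        self.tract_of_obs = counts["tract_id"].map(tindex).to_numpy(int)
        self.n_tracts = len(self.tract_ids)
        self.n_obs = len(counts)
        # observations are sorted by tract: contiguous slices per tract
        self.obs_start = np.searchsorted(self.tract_of_obs, np.arange(self.n_tracts))
        self.obs_stop = np.searchsorted(
            self.tract_of_obs, np.arange(self.n_tracts), side="right"
        )

        if spec.re_prior == "car":
            if graph is None:
                raise ValueError("re_prior='car' requires the tract graph")
            edges = []
            for a, b in graph.edges:
                if a in tindex and b in tindex:
                    edges.append((tindex[a], tindex[b]))
            self.edges = np.array(sorted(edges), dtype=int).reshape(-1, 2)
        else:
            self.edges = np.zeros((0, 2), dtype=int)
        self.degree = np.zeros(self.n_tracts)
        np.add.at(self.degree, self.edges.ravel(), 1.0)
        self.isolated = self.degree == 0
        self.component = self._components()
        # icar rank = (#non-isolated) - (#components of size >= 2); isolated
        # tracts contribute a proper Normal(0, 1/tau) with full rank
        comp_ids, comp_sizes = np.unique(self.component, return_counts=True)
        self.n_components_icar = int(np.sum(comp_sizes >= 2))
        self.icar_rank = int(
            np.sum(~self.isolated) - self.n_components_icar + np.sum(self.isolated)
        )
        self.colors = self._greedy_colors()
        # neighbor structure as CSR-like arrays for fast neighbor sums
        order = np.argsort(
            np.concatenate([self.edges[:, 0], self.edges[:, 1]]), kind="stable"
        )
        ends = np.concatenate([self.edges[:, 1], self.edges[:, 0]])[order]
        self.nbr_flat = ends
        srcs = np.concatenate([self.edges[:, 0], self.edges[:, 1]])[order]
        self.nbr_start = np.searchsorted(srcs, np.arange(self.n_tracts))
        self.nbr_stop = np.searchsorted(srcs, np.arange(self.n_tracts), side="right")

    def _components(self):
        parent = np.arange(self.n_tracts)

        def find(x):
            root = x
            while parent[root] != root:
                root = parent[root]
            while parent[x] != root:
                parent[x], x = root, parent[x]
            return root

        for a, b in self.edges:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
        return np.array([find(i) for i in range(self.n_tracts)])

    def _greedy_colors(self):
        color = np.full(self.n_tracts, -1)
        adj = [[] for _ in range(self.n_tracts)]
        for a, b in self.edges:
            adj[a].append(b)
            adj[b].append(a)
        for i in range(self.n_tracts):
            used = {color[j] for j in adj[i] if color[j] >= 0}
            c = 0
            while c in used:
                c += 1
            color[i] = c
        return [np.flatnonzero(color == c) for c in range(color.max() + 1)]

    def neighbor_sum(self, nu, sites):
        out = np.zeros(len(sites))
        for k, i in enumerate(sites):
            out[k] = nu[self.nbr_flat[self.nbr_start[i] : self.nbr_stop[i]]].sum()
        return out


# ---------------------------------------------------------------------------
# likelihood


def _base_logpmf(y, mu, family, shape):
    if family == "poisson":
        return dist.poisson_logpmf(y, mu)
    if family == "nb":
        return dist.nb_logpmf(y, mu, shape)
    if family == "cmp":
        lam = dist.cmp_lambda_for_mean(mu, shape)
        return dist.cmp_logpmf(y, lam, shape)
    raise ValueError(family)


def pointwise_loglik_arrays(y, e, eta_count, eta_zero, spec: ModelSpec, shape):
    """Vectorized per-observation log-likelihood; e = 0 means P(y=0) = 1."""
    y = np.asarray(y, dtype=float)
    e = np.asarray(e, dtype=float)
    out = np.zeros(np.broadcast_shapes(y.shape, np.shape(eta_count)))
    active = e > 0
    mu = e[active] * np.exp(np.asarray(eta_count)[..., active])
    base = _base_logpmf(y[active], mu, spec.base_family, shape)
    if spec.zero_inflated:
        base0 = _base_logpmf(np.zeros_like(mu), mu, spec.base_family, shape)
        pi = expit(np.asarray(eta_zero)[..., active])
        out[..., active] = dist.zi_logpmf(y[active], base, base0, pi)
    else:
        out[..., active] = base
    if np.any(~active):
        out[..., ~active] = np.where(y[~active] == 0, 0.0, -np.inf)
    return out


def loglik_observation(y, e, design_row, params: dict, spec: ModelSpec):
    """Log-likelihood of a single stratum.

    ``params`` carries beta_count (array in design order), nu (scalar tract
    effect), and for zi families beta_zero / nu_zero; shape for nb/cmp.
    """
    if e < 0:
        raise ValueError("expected count must be >= 0")
    x = np.asarray(design_row, dtype=float)
    eta_c = float(x @ np.asarray(params["beta_count"]) + params.get("nu", 0.0))
    eta_z = float(
        x @ np.asarray(params.get("beta_zero", np.zeros_like(x)))
        + params.get("nu_zero", 0.0)
    )
    out = pointwise_loglik_arrays(
        np.array([y]), np.array([e]), np.array([eta_c]), np.array([eta_z]),
        spec, params.get("shape"),
    )
    return float(out[0])


# ---------------------------------------------------------------------------
# sampler


class _ChainState:
    def __init__(self, data: _ModelData, spec: ModelSpec, priors: Priors, rng):
        self.rng = rng
        p = data.X.shape[1]
        # moment-based starting values keep the short warmup honest
        rate = max(data.y[data.active].sum(), 0.5) / max(data.e[data.active].sum(), 1e-12)
        self.beta_c = np.zeros(p)
        self.beta_c[0] = np.log(rate)
        self.nu_c = self._init_nu(data, rate)
        self.tau_c = 1.0 / max(np.var(self.nu_c), 0.05)
        if spec.zero_inflated:
            frac0 = np.mean(data.y[data.active] == 0)
            self.beta_z = np.zeros(p)
            self.beta_z[0] = np.log(max(frac0, 0.02) / max(1 - frac0, 0.02))
            self.nu_z = np.zeros(data.n_tracts)
            self.tau_z = 1.0
        else:
            self.beta_z = None
            self.nu_z = None
            self.tau_z = None
        self.shape = 2.0 if spec.has_shape else None
        # adaptive proposal scales
        self.s_beta_c = 0.05
        self.s_beta_z = 0.1
        self.s_nu_c = np.full(data.n_tracts, 0.3)
        self.s_nu_z = np.full(data.n_tracts, 0.5)
        self.s_shape = 0.3
        # proposal shape: Cholesky factor adapted from warmup history (AM)
        self.beta_c_chol = np.eye(p)
        self.beta_z_chol = np.eye(p)
        self._beta_hist_c = []
        self._beta_hist_z = []

    def _init_nu(self, data, rate):
        nu = np.zeros(data.n_tracts)
        for i in range(data.n_tracts):
            sl = slice(data.obs_start[i], data.obs_stop[i])
            nu[i] = np.log(
                (data.y[sl].sum() + 0.5) / (rate * data.e[sl].sum() + 0.5)
            )
        nu -= nu.mean()
        return np.clip(nu, -4.0, 4.0)


def _recenter(nu, data: _ModelData):
    """Component-wise zero mean for non-isolated tracts (ICAR identification)."""
    for comp in np.unique(data.component):
        idx = np.flatnonzero((data.component == comp) & ~data.isolated)
        if len(idx) >= 2:
            nu[idx] -= nu[idx].mean()
    return nu


def _run_chain(data, spec, priors, mcmc, chain_idx, progress=False):
    rng = np.random.default_rng(
        np.random.SeedSequence([int(mcmc.seed) % (2**31), 17, chain_idx])
    )
    st = _ChainState(data, spec, priors, rng)
    warm = mcmc.warmup
    kept = {
        "beta_count": [], "nu_count": [], "tau_count": [],
    }
    if spec.zero_inflated:
        kept["beta_zero"] = []
        kept["nu_zero"] = []
        kept["tau_zero"] = []
    if spec.has_shape:
        kept["shape"] = []

    eta_c = data.X @ st.beta_c + st.nu_c[data.tract_of_obs]
    eta_z = (
        data.X @ st.beta_z + (st.nu_c if spec.share_random_effect else st.nu_z)[data.tract_of_obs]
        if spec.zero_inflated
        else np.zeros(data.n_obs)
    )
    cur_ll = pointwise_loglik_arrays(data.y, data.e, eta_c, eta_z, spec, st.shape)

    def total_ll(ec, ez, shape):
        return pointwise_loglik_arrays(data.y, data.e, ec, ez, spec, shape)

    for it in range(mcmc.iterations):
        adapt = it < warm
        gamma = min(0.25, 2.0 / np.sqrt(it + 10)) if adapt else 0.0

        # ---- fixed effects (covariance-adaptive RW blocks, several sweeps)
        for _ in range(3):
            prop = st.beta_c + st.s_beta_c * (
                st.beta_c_chol @ rng.standard_normal(len(st.beta_c))
            )
            ec = data.X @ prop + st.nu_c[data.tract_of_obs]
            ll = total_ll(ec, eta_z, st.shape)
            dprior = (st.beta_c @ st.beta_c - prop @ prop) / (2 * priors.beta_sd**2)
            acc = np.log(rng.random()) < ll.sum() - cur_ll.sum() + dprior
            if acc:
                st.beta_c, eta_c, cur_ll = prop, ec, ll
            if adapt:
                st.s_beta_c = float(np.exp(np.log(st.s_beta_c) + gamma * ((1.0 if acc else 0.0) - 0.234)))

            if spec.zero_inflated:
                prop = st.beta_z + st.s_beta_z * (
                    st.beta_z_chol @ rng.standard_normal(len(st.beta_z))
                )
                nuz = st.nu_c if spec.share_random_effect else st.nu_z
                ez = data.X @ prop + nuz[data.tract_of_obs]
                ll = total_ll(eta_c, ez, st.shape)
                dprior = (st.beta_z @ st.beta_z - prop @ prop) / (2 * priors.beta_sd**2)
                acc = np.log(rng.random()) < ll.sum() - cur_ll.sum() + dprior
                if acc:
                    st.beta_z, eta_z, cur_ll = prop, ez, ll
                if adapt:
                    st.s_beta_z = float(np.exp(np.log(st.s_beta_z) + gamma * ((1.0 if acc else 0.0) - 0.234)))
        if adapt:
            st._beta_hist_c.append(st.beta_c.copy())
            if spec.zero_inflated:
                st._beta_hist_z.append(st.beta_z.copy())
            if len(st._beta_hist_c) >= 60 and it % 20 == 0:
                st.beta_c_chol = _safe_chol(np.array(st._beta_hist_c[-300:]))
                if spec.zero_inflated:
                    st.beta_z_chol = _safe_chol(np.array(st._beta_hist_z[-300:]))

        # ---- tract effects, count part
        eta_c, eta_z, cur_ll = _update_nu(
            data, spec, priors, st, rng, "count", eta_c, eta_z, cur_ll, gamma
        )
        st.nu_c = _recenter(st.nu_c, data) if spec.re_prior == "car" else st.nu_c
        # recentring shifts eta; rebuild to keep the cache exact
        eta_c = data.X @ st.beta_c + st.nu_c[data.tract_of_obs]
        if spec.zero_inflated and spec.share_random_effect:
            eta_z = data.X @ st.beta_z + st.nu_c[data.tract_of_obs]
        cur_ll = total_ll(eta_c, eta_z, st.shape)

        # ---- tract effects, zero part
        if spec.zero_inflated and not spec.share_random_effect:
            eta_c, eta_z, cur_ll = _update_nu(
                data, spec, priors, st, rng, "zero", eta_c, eta_z, cur_ll, gamma
            )
            if spec.re_prior == "car":
                st.nu_z = _recenter(st.nu_z, data)
                eta_z = data.X @ st.beta_z + st.nu_z[data.tract_of_obs]
                cur_ll = total_ll(eta_c, eta_z, st.shape)

        # ---- precisions (conjugate)
        st.tau_c = _gibbs_tau(st.nu_c, data, spec, priors, rng)
        if spec.zero_inflated and not spec.share_random_effect:
            st.tau_z = _gibbs_tau(st.nu_z, data, spec, priors, rng)

        # ---- dispersion / decay
        if spec.has_shape:
            prop = float(np.exp(np.log(st.shape) + st.s_shape * rng.standard_normal()))
            if prop > priors.nb_shape_floor:
                ll = total_ll(eta_c, eta_z, prop)
                if spec.base_family == "nb":
                    dpr = (priors.nb_shape_a * (np.log(prop) - np.log(st.shape))
                           - priors.nb_shape_b * (prop - st.shape))
                else:  # lognormal prior on the CMP decay
                    dpr = -((np.log(prop) - priors.cmp_nu_logmean) ** 2
                            - (np.log(st.shape) - priors.cmp_nu_logmean) ** 2) / (
                        2 * priors.cmp_nu_logsd**2
                    )
                acc = np.log(rng.random()) < ll.sum() - cur_ll.sum() + dpr
                if acc:
                    st.shape, cur_ll = prop, ll
                if adapt:
                    st.s_shape = float(np.exp(np.log(st.s_shape) + gamma * ((1.0 if acc else 0.0) - 0.44)))

        if not np.isfinite(cur_ll.sum()):
            raise RuntimeError(
                f"non-finite posterior at iteration {it} (chain {chain_idx}); "
                "check offsets and starting values"
            )

        if it >= warm and (it - warm) % mcmc.thin == 0:
            kept["beta_count"].append(st.beta_c.copy())
            kept["nu_count"].append(st.nu_c.copy())
            kept["tau_count"].append(st.tau_c)
            if spec.zero_inflated:
                kept["beta_zero"].append(st.beta_z.copy())
                kept["nu_zero"].append(
                    (st.nu_c if spec.share_random_effect else st.nu_z).copy()
                )
                kept["tau_zero"].append(
                    st.tau_c if spec.share_random_effect else st.tau_z
                )
            if spec.has_shape:
                kept["shape"].append(st.shape)

    return {k: np.asarray(v) for k, v in kept.items()}


def _safe_chol(history: np.ndarray) -> np.ndarray:
    cov = np.cov(history.T) + 1e-6 * np.eye(history.shape[1])
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        return np.diag(np.std(history, axis=0) + 1e-3)


def _update_nu(data, spec, priors, st, rng, part, eta_c, eta_z, cur_ll, gamma):
    """Chromatic single-site random-walk update of one tract-effect vector."""
    nu = st.nu_c if part == "count" else st.nu_z
    scales = st.s_nu_c if part == "count" else st.s_nu_z
    tau = st.tau_c if part == "count" else st.tau_z
    shared = spec.zero_inflated and spec.share_random_effect and part == "count"
    for sites in data.colors:
        dnu = scales[sites] * rng.standard_normal(len(sites))
        # prior log-density change
        if spec.re_prior == "car":
            nbr = data.neighbor_sum(nu, sites)
            m = data.degree[sites]
            old, new = nu[sites], nu[sites] + dnu
            dprior = -0.5 * tau * (
                m * new**2 - 2 * new * nbr - (m * old**2 - 2 * old * nbr)
            )
            iso = data.isolated[sites]
            dprior[iso] = -0.5 * tau * (new[iso] ** 2 - old[iso] ** 2)
        else:
            old, new = nu[sites], nu[sites] + dnu
            dprior = -0.5 * tau * (new**2 - old**2)
        # likelihood change over the strata of the proposed tracts
        obs_idx = np.concatenate(
            [np.arange(data.obs_start[i], data.obs_stop[i]) for i in sites]
        )
        seg = np.cumsum([0] + [data.obs_stop[i] - data.obs_start[i] for i in sites])[:-1]
        d_obs = np.repeat(dnu, [data.obs_stop[i] - data.obs_start[i] for i in sites])
        if part == "count":
            ec_new = eta_c[obs_idx] + d_obs
            ez_new = eta_z[obs_idx] + d_obs if shared else eta_z[obs_idx]
        else:
            ec_new = eta_c[obs_idx]
            ez_new = eta_z[obs_idx] + d_obs
        ll_new = pointwise_loglik_arrays(
            data.y[obs_idx], data.e[obs_idx], ec_new, ez_new, spec, st.shape
        )
        dll = np.add.reduceat(ll_new - cur_ll[obs_idx], seg)
        accept = np.log(rng.random(len(sites))) < dll + dprior
        if accept.any():
            nu[sites[accept]] += dnu[accept]
            obs_accept = np.repeat(
                accept, [data.obs_stop[i] - data.obs_start[i] for i in sites]
            )
            upd = obs_idx[obs_accept]
            if part == "count":
                eta_c[upd] = ec_new[obs_accept]
                if shared:
                    eta_z[upd] = ez_new[obs_accept]
            else:
                eta_z[upd] = ez_new[obs_accept]
            cur_ll[upd] = ll_new[obs_accept]
        if gamma > 0:
            scales[sites] = np.clip(
                scales[sites] * np.exp(gamma * (accept.astype(float) - 0.44)),
                1e-3,
                10.0,
            )
    return eta_c, eta_z, cur_ll


def _gibbs_tau(nu, data, spec, priors, rng):
    if spec.re_prior == "car":
        q = dist.car_quadform(nu, data.edges) + float(nu[data.isolated] @ nu[data.isolated])
        rank = data.icar_rank
    else:
        q = float(nu @ nu)
        rank = data.n_tracts
    return float(rng.gamma(priors.tau_shape + rank / 2.0, 1.0 / (priors.tau_rate + q / 2.0)))


def fit(
    counts: pd.DataFrame,
    spec: ModelSpec,
    mcmc: McmcSettings | None = None,
    graph: TractGraph | None = None,
    priors: Priors | None = None,
) -> PosteriorDraws:
    """Fit the model by MCMC; returns post-warmup draws for all parameters.

    ``counts`` is the full stratified grid with y_/e_ columns for the chosen
    outcome; ``graph`` supplies adjacency when re_prior='car'. Runs are
    deterministic for a fixed McmcSettings.seed. A split-R-hat above 1.05 on
    any monitored parameter sets ``rhat_warning`` on the result.
    """
    mcmc = mcmc or McmcSettings()
    priors = priors or Priors()
    data = _ModelData(counts, spec, graph)
    chains = [
        _run_chain(data, spec, priors, mcmc, c) for c in range(mcmc.chains)
    ]
    params = {k: np.stack([ch[k] for ch in chains]) for k in chains[0]}
    draws = PosteriorDraws(
        params=params,
        tract_ids=data.tract_ids,
        design_columns=data.design_columns,
        spec=spec,
        mcmc=mcmc,
        obs_index=data.counts[["tract_id", "species", "period"]],
    )
    if mcmc.chains >= 2:
        diag = diagnostics(draws, scalars_only=True)
        worst = diag["rhat"].max()
        if np.isfinite(worst) and worst > 1.05:
            draws.rhat_warning = True
            log.warning("max split-R-hat %.3f > 1.05: chains may not have converged", worst)
    return draws


def diagnostics(draws: PosteriorDraws, scalars_only: bool = False) -> pd.DataFrame:
    """Split-R-hat and ESS ratio per parameter (requires >= 2 chains).

    Zero-variance (constant) chains yield NaN with a warning rather than an
    error. Parameters with rhat > 1.01 are flagged in the ``flag`` column.
    """
    first = next(iter(draws.params.values()))
    if first.shape[0] < 2:
        raise ValueError("R-hat requires at least 2 chains")
    import arviz as az

    rows = []
    total = first.shape[0] * first.shape[1]
    for name, a in draws.params.items():
        if a.ndim == 2:
            entries = {name: a}
        elif scalars_only:
            continue
        else:
            labels = draws.tract_ids if name.startswith("nu") else draws.design_columns
            entries = {f"{name}[{lab}]": a[:, :, k] for k, lab in enumerate(labels)}
        for label, arr in entries.items():
            if np.allclose(arr.var(axis=1), 0.0):
                warnings.warn(f"parameter {label}: zero-variance chains, R-hat undefined")
                rows.append({"parameter": label, "rhat": np.nan, "ess_ratio": np.nan})
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rhat = float(az.rhat(arr[None, ...][0]))
                ess = float(az.ess(arr[None, ...][0]))
            rows.append({"parameter": label, "rhat": rhat, "ess_ratio": ess / total})
    out = pd.DataFrame(rows)
    out["flag"] = out["rhat"] > 1.01
    return out
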