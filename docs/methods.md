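# Methods

## Observation model

The unit of analysis is the stratum (census tract `i`, species, five-year
period). The outcome is either the deduplicated visit count or the cancer
count; cancer records are a flagged subset of visits (one animal-year is one
visit, cancer taking precedence when an animal has both kinds of records in
a year). Counts follow a zero-inflated mixture: a structural zero with
probability `pi_ij` (tracts whose owners never use the hospital), otherwise
a draw from a count family with mean `mu_ij = e_ij * R_ij`. Both the
log-relative-risk and the logit of the structural-zero probability are
linear in species and period (treatment coding; reference levels feline and
the first period) plus a tract random effect. The zero and count parts carry
*separate* coefficient vectors and separate tract-effect vectors by default
(`share_random_effect=True` collapses them): this is the more general
reading of a shared-symbol formula block and matches how brms-style
zero-inflated regressions are parameterized.

Supported families: Poisson, negative binomial in the mean/shape
parameterization (variance `mu + mu^2/phi`), and Conway-Maxwell-Poisson.
The CMP normalizer is a truncated series (stop when the next term is below
1e-12 of the running sum); because CMP's natural parameter is not its mean,
a bisection solve (tolerance 1e-8) maps the target mean `e * R` to the rate
`lambda`, so `mu = e * R` means the same thing in every family. With `e = 0`
the likelihood degenerates to a point mass at zero.

## Expected counts

`e_ij = (total count / total population) * population_ij`, computed
separately per outcome, with `population_ij = households_i x 1.6` (dogs) or
`x 1.7` (cats). This is the standardized-incidence-ratio convention: it is
the only reading under which `e` is an "expected" count — the global rate
times the stratum's population — and it makes `sum(e) = sum(y)` an exact,
testable invariant, centring the relative risk at 1. Populations are treated
as constant over periods (census households are a single snapshot);
per-period household inputs are accepted when available. A consequence worth
remembering: because the offset is recomputed from the data, the *intercept*
absorbs the log of the mean relative risk and is not a recoverable quantity
in simulation studies; all other fixed effects are.

## Priors and random effects

Coefficients get Normal(0, 5^2); precisions tau get Gamma(1, 0.01); the NB
shape gets Gamma(0.01, 0.01) floored at 1e-4; the CMP decay gets
LogNormal(0, 1). All are configurable (`Priors`). The intrinsic CAR prior is
the pairwise-difference form with precision `tau (D - W)`; its full
conditional is Normal(neighbor mean, `1/(m_i tau)`). It is improper —
invariant to a constant shift within each connected graph component — so the
effects are identified by re-centring each component to mean zero at every
iteration, the same device established CAR samplers use; isolated tracts
(no neighbors) get a proper Normal(0, 1/tau) and are left out of the
centring. On a graph with no edges the CAR prior therefore reduces exactly
to the exchangeable prior (asserted in the tests).

## Sampler

An adaptive Metropolis-within-Gibbs scheme:

- fixed-effect blocks: joint random-walk proposals whose covariance is the
  empirical covariance of the warmup history (Cholesky factor refreshed
  every 20 warmup iterations) and whose scale adapts toward 23% acceptance;
  three sweeps per iteration because these are the cheapest updates;
- tract effects: single-site random-walk updates batched by a greedy graph
  coloring — same-color tracts are conditionally independent under the
  pairwise CAR factorization, so each color class is proposed and
  accepted/rejected as a vector; per-site scales adapt toward 44%
  acceptance during warmup only;
- precisions: conjugate Gamma draws (rank = n - number of components for
  the CAR part, plus full rank for isolated tracts);
- NB shape / CMP decay: log-scale random walk.

Defaults: 4 chains, 4,000 iterations per chain with
the first 25% discarded as burn-in ("iterations" is read as the total per
chain). Chains are seeded independently from one seed and run sequentially,
so results are exactly reproducible. Convergence is summarized by split
R-hat and the ESS/total ratio (via arviz); any monitored R-hat above 1.05
sets a warning flag on the returned draws. Zero-variance chains yield NaN
R-hat with a warning rather than an error.

Moment-based starting values (global log-rate intercept, crude per-tract
log SIRs clipped to [-4, 4], observed zero fraction for the zero-model
intercept) keep short warmups honest.

## Model comparison

PSIS-LOO is implemented as published: per observation, raw importance
ratios `r_s = exp(-ll_s)`; the largest `ceil(min(0.2 S, 3 sqrt(S)))` ratios
are replaced by expected order statistics of a generalized Pareto
distribution fitted to the exceedances by the Zhang-Stephens
profile-posterior method, then capped at the raw maximum;
`elpd_i = log(sum w ll-weighted) - log(sum w)`; `SE = sqrt(N var(elpd_i))`.
The tail-shape k is reported per observation (k > 0.7 flagged). Rankings
report pairwise-pointwise `elpd_diff` and its SE against the best model.
With one latent effect per tract and only a handful of strata per tract,
high-k observations are common — exactly as with brms + loo on such models —
so the comparison table carries `max_pareto_k`/`n_bad_k` rather than hiding
them. Tests cross-check the implementation against arviz's PSIS-LOO and
against the closed-form exact LOO of a conjugate Gamma-Poisson model.

## Catchment delineation

`q_i` is the fraction of posterior draws with `nu_i > 0` (equivalently
`RR_i > 1`), computed from the *count-model* effect: case intensity, not
the structural-zero propensity, is what makes a tract a contributor
(configurable to the zero effect or their sum). Membership uses the closed
rule `q_i >= threshold`, so memberships are nested across thresholds. The
primary area is the connected component of members containing the
hospital's tract; detached members form the secondary area; if the hospital
tract is not a member, the largest component (ties broken by proximity)
is primary. Reported percentages are rounded half-up to one decimal, with
full precision retained alongside. Per-period catchments come from separate
refits on each period's subset (the species term stays; the period term
drops out), keeping period estimates independent; the combined CA is the
intersection of the period memberships.

## Synthetic scenarios

The generator emulates the structure of the target registry at desk scale:

- 20 x 20 square tracts (queen contiguity), hospital at the center;
  households uniform in [200, 800]; income = 95,000 - 150 * distance_km +
  Normal(0, 12,000), floored at 10,000 USD — a distance-decaying surface
  with realistic scatter around the registry's income range;
- tract fields drawn *exactly* from the intrinsic CAR distribution via the
  graph-Laplacian eigendecomposition (coefficients Normal(0, 1/(tau l_k))
  on positive-eigenvalue eigenvectors; null-space coefficients zero, which
  is the hard sum-to-zero constraint). tau = 0.4 gives a marginal spatial SD
  of about 0.9 on this grid, i.e. tract relative risks mostly within
  e^(+-1.8) — an urban/rural contrast of realistic magnitude;
- visit counts: ZINB by default (shape 5, baseline structural-zero
  probability 0.18), species rate ratio 3.0 and period ratios
  (1.0, 1.1, 1.3); baseline rate chosen so visit totals are of order 10^4
  over 3,200 strata;
- cancer counts: binomial thinning of visits (baseline fraction 0.118,
  with species/period adjustments so the cancer outcome carries rate ratios
  2.6 and (0.9, 1.2, 1.0)) — thinning guarantees cancer <= visits per
  stratum and, by the NB thinning property, preserves the ZINB form;
- optional expansion to raw per-animal records, with repeat same-year
  visits injected at rate 0.3 to exercise deduplication;
- the true catchment is defined as `{i : nu_i > 0}`, which makes
  delineation recovery well-posed;
- a separate membership generator draws tract CA membership from a known
  logistic law in centred distance and income (with interaction) for the
  determinant analysis.

What the default scenario does *not* emulate: the spatial field is drawn
from the ICAR prior itself and is therefore smooth but *independent of
distance and income*. Passing recovery tests shows the model and the
delineation machinery work; it does not show that a real catchment looks
like this. In particular, on this scenario the fitted CA is unrelated to
the covariates (AUC near 0.5) and its secondary area is proportionally
larger than a distance-driven catchment would produce; the determinant
stage is therefore validated on the dedicated logistic-law scenario, where
signs and the AUC gain from adding income and the interaction are
recoverable. Real geographies with irregular polygons, road-network
distances and census idiosyncrasies are out of scope.

## Problem sizes and numerical choices

The bundled analyses and the acceptance script run the study-scale scenario
(3,200 strata, 400 tracts) at 4 chains x 1,000 iterations — posterior
means and exceedance probabilities are stable at this size, and the full
4 x 4,000 defaults remain available through `McmcSettings`. At these reduced
settings the weakly identified parts of sparse fits — above all the
zero-model precision on the cancer outcome, where 80% of strata are zero —
can keep R-hat above 1.05; the fit flags this honestly rather than masking
it, the spatial field that drives delineation is unaffected (recovery
r > 0.8 for both outcomes), but the zero/count split of thinly informed
coefficients (e.g. the cancer species effect) should be read with its
posterior spread in mind. Degenerate inputs are defined, not patched:
`e = 0` strata contribute point mass at zero, empty memberships warn and
return empty areas, constant chains give NaN diagnostics, perfect
separation in the logistic stage raises an error naming the condition.

In the determinant stage, covariates are centred (study convention) and by
default *also* scaled to unit SD: a per-km odds ratio on a 0-233 km range
is numerically tiny and unreadable, while per-SD units make the distance
and income effects comparable; centring and scaling constants are always
recorded so either convention can be reproduced exactly (`--no-scale`
equivalent: `standardize=False`). Sequential deviance is the type-I
(terms-added-in-order) decomposition in the order distance, income,
interaction. AUC uses the Mann-Whitney rank statistic with half-credit for
ties; Wald 95% intervals on the log-odds scale.
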