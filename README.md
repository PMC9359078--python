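# vetcatch

Data-driven delineation of a veterinary hospital's catchment area (CA) from
registry counts, with Bayesian hierarchical count models, and analysis of the
factors that shape the catchment.

Hospital registries are a major data source for companion-animal cancer
epidemiology, but patients do not arrive at a hospital at random: distance,
owner income and other factors shape which census tracts actually contribute
records. Inferences about incidence or risk that ignore the catchment are
biased. This package implements a probabilistic, registry-driven way to draw
the catchment boundary and to quantify what drives it, exercised end-to-end
on synthetic registries with known ground truth.

## Model

Counts of registry records (cancer cases or total visits) per census tract
`i` and species/period stratum `j` follow a zero-inflated count model

```
Y_ij = 0            with probability pi_ij
Y_ij ~ F(mu_ij)     with probability 1 - pi_ij

mu_ij        = e_ij * R_ij
log R_ij     = b0 + b_species + b_period + nu_i
logit pi_ij  = g0 + g_species + g_period + omega_i
```

with `F` Poisson, negative binomial (mean/shape) or mean-parameterized
Conway-Maxwell-Poisson, and `e_ij` an expected count from a global rate times
the stratum's estimated animal population (1.6 dogs / 1.7 cats per household).
Tract effects `nu` (and `omega`) get either an exchangeable Normal(0, 1/tau)
prior or an intrinsic conditional-autoregressive (CAR) prior, under which
each tract's effect is conditionally Normal around the mean of its
neighbors' with precision `m_i * tau` (`m_i` = number of adjacent tracts).
Candidate models (family x prior) are ranked by PSIS-LOO ELPD. From the
selected fit, each tract's exceedance probability
`q_i = Pr(RR_i > 1 | data) = Pr(nu_i > 0 | data)` is thresholded (0.90 by
disease-mapping convention; 0.80-0.95 explored) to form the CA, which is
split into a primary area (the connected block holding the hospital) and
detached secondary tracts. A logistic regression of CA membership on
centred distance-to-hospital and average household income (plus their
interaction) with ROC/AUC quantifies the catchment's determinants.

Fitting uses an adaptive Metropolis-within-Gibbs sampler written for this
model family (covariance-adaptive blocks for the fixed effects, vectorized
graph-coloring updates for the tract effects, conjugate Gibbs draws for the
precisions); see `docs/methods.md` for the numerical details.

## Worked example

```python
from vetcatch import registry, synthdata
from vetcatch.spatial_model import ModelSpec, McmcSettings, fit
from vetcatch.catchment import exceedance, delineate

cfg = synthdata.ScenarioConfig(seed=1)          # 20x20 tracts, 2 species, 4 periods
graph, counts, truth = synthdata.make_scenario(cfg)
counts = registry.expected_counts(counts)       # global-rate offsets, sum(e) == sum(y)

spec = ModelSpec(family="zinb", re_prior="car", outcome="visits")
draws = fit(counts, spec, McmcSettings(chains=4, iterations=1000, seed=5), graph=graph)
members = delineate(exceedance(draws), 0.90)
```

On this scenario (3,200 strata; 10,215 visits; 197 of 400 tracts truly in
the catchment, i.e. simulated `nu > 0`) the run above recovers the spatial
field with Pearson r = 0.93 against the simulated truth, estimates the
canine/feline visit rate ratio at 2.9 (simulated: 3.0), and the
0.90-threshold CA classifies tracts with sensitivity 0.65 and specificity
0.99. The delineated visits CA captures 71% of all records while covering
only 33% of the tracts, and ranking all family x prior candidates by
PSIS-LOO puts ZINB with the CAR prior first — the zero-heavy, spatially
correlated structure is detected from the data alone.

The numbered scripts under `analysis/` run the same pipeline as a narrative:
`01_simulate.py` (scenario with ground truth), `02_prepare.py` (buffer,
deduplication, stratification, offsets), `03_fit_models.py` (model grid +
PSIS-LOO ranking), `04_delineate.py` (exceedance CAs, coverage, concordance,
per-period stability), `05_determinants.py` (distance x income logistic
analysis with ROC). Each prints what it found and writes tables under
`results/`.

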