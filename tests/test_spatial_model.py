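import numpy as np
import pandas as pd
import pytest

from vetcatch import registry
from vetcatch.distributions import nb_logpmf, poisson_logpmf, zi_logpmf
from vetcatch.region import Tract, TractGraph
from vetcatch.spatial_model import (
    McmcSettings,
    ModelSpec,
    PosteriorDraws,
    build_design,
    diagnostics,
    fit,
    loglik_observation,
    pointwise_loglik_arrays,
)
from vetcatch.synthdata import CoefficientSet, ScenarioConfig, make_grid_region, simulate_counts


class TestLoglikObservation:
    def test_null_model_is_poisson_at_offset(self):
        spec = ModelSpec(family="poisson", re_prior="exchangeable")
        params = {"beta_count": np.zeros(1), "nu": 0.0}
        got = loglik_observation(2, 2.0, [1.0], params, spec)
        assert got == pytest.approx(float(poisson_logpmf(2, 2.0)), abs=1e-12)

    def test_species_coefficient_doubles_mean(self):
        spec = ModelSpec(family="poisson", re_prior="exchangeable")
        params = {"beta_count": np.array([0.0, np.log(2.0)]), "nu": 0.0}
        got = loglik_observation(3, 1.5, [1.0, 1.0], params, spec)
        assert got == pytest.approx(float(poisson_logpmf(3, 3.0)), abs=1e-12)

    def test_zinb_composes_zi_and_nb(self):
        spec = ModelSpec(family="zinb", re_prior="exchangeable")
        params = {
            "beta_count": np.array([0.2]),
            "beta_zero": np.array([-0.4]),
            "nu": 0.1,
            "nu_zero": -0.3,
            "shape": 1.8,
        }
        e, y = 2.5, 4
        mu = e * np.exp(0.2 + 0.1)
        pi = 1.0 / (1.0 + np.exp(0.4 + 0.3))
        expected = zi_logpmf(
            np.array([y]),
            nb_logpmf(y, mu, 1.8),
            nb_logpmf(0, mu, 1.8),
            pi,
        )[0]
        got = loglik_observation(y, e, [1.0], params, spec)
        assert got == pytest.approx(float(expected), abs=1e-12)

    def test_zero_expected_count_forces_zero(self):
        spec = ModelSpec(family="poisson", re_prior="exchangeable")
        params = {"beta_count": np.zeros(1)}
        assert loglik_observation(0, 0.0, [1.0], params, spec) == 0.0
        assert loglik_observation(2, 0.0, [1.0], params, spec) == -np.inf

    def test_zi_with_pi_zero_equals_base_family(self):
        y = np.array([0.0, 1, 4, 0, 2])
        e = np.full(5, 2.0)
        eta_c = np.linspace(-0.5, 0.5, 5)
        zinb = pointwise_loglik_arrays(
            y, e, eta_c, np.full(5, -745.0), ModelSpec(family="zinb"), 2.0
        )
        nb = pointwise_loglik_arrays(
            y, e, eta_c, np.zeros(5), ModelSpec(family="nb"), 2.0
        )
        np.testing.assert_allclose(zinb, nb, atol=1e-12)


def _two_period_scheme():
    return registry.PeriodScheme((("P1", 2000, 2009), ("P2", 2010, 2019)))


def _poisson_species_counts(n_side=5, beta_species=np.log(2.0), seed=21):
    scheme = _two_period_scheme()
    cfg = ScenarioConfig(
        grid_rows=n_side,
        grid_cols=n_side,
        hospital_cell=(n_side // 2, n_side // 2),
        family="poisson",
        beta_count=CoefficientSet(0.0, beta_species, (0.0,)),
        beta_zero=CoefficientSet(-np.inf, 0.0, (0.0,)),
        cancer_period_shift=(0.0,),
        visit_rate=0.01,
        scheme=scheme,
        seed=seed,
    )
    g = make_grid_region(cfg)
    nu0 = {t: 0.0 for t in g.tract_ids}
    counts = registry.expected_counts(simulate_counts(g, nu0, cfg))
    return g, counts, scheme


class TestFit:
    def test_poisson_exchangeable_recovers_species_effect(self):
        # 100 strata (25 tracts x 2 species x 2 periods), true log RR = log 2
        _, counts, _ = _poisson_species_counts()
        spec = ModelSpec(family="poisson", re_prior="exchangeable", outcome="visits")
        draws = fit(counts, spec, McmcSettings(chains=2, iterations=1500, seed=3))
        k = draws.design_columns.index("species_canine")
        est = draws.stacked("beta_count")[:, k].mean()
        assert abs(est - np.log(2.0)) < 0.15

    def test_same_seed_reproduces_draws(self, small_scenario):
        graph, counts, _, _ = small_scenario
        spec = ModelSpec(family="zinb", re_prior="car", outcome="visits")
        m = McmcSettings(chains=2, iterations=200, seed=12)
        d1 = fit(counts, spec, m, graph=graph)
        d2 = fit(counts, spec, m, graph=graph)
        for k in d1.params:
            np.testing.assert_array_equal(d1.params[k], d2.params[k])

    def test_car_on_edgeless_graph_equals_exchangeable(self):
        g, counts, _ = _poisson_species_counts(n_side=3)
        empty = TractGraph({t: g.tracts[t] for t in g.tracts}, set(), g.hospital_point)
        m = McmcSettings(chains=1, iterations=300, seed=5)
        d_car = fit(counts, ModelSpec(family="poisson", re_prior="car"), m, graph=empty)
        d_ex = fit(counts, ModelSpec(family="poisson", re_prior="exchangeable"), m)
        # with no edges every tract is isolated: iid Normal(0, 1/tau) either way
        for k in d_car.params:
            np.testing.assert_array_equal(d_car.params[k], d_ex.params[k])

    def test_car_requires_graph(self, small_scenario):
        _, counts, _, _ = small_scenario
        with pytest.raises(ValueError, match="graph"):
            fit(counts, ModelSpec(family="poisson", re_prior="car"))

    def test_nu_draws_centered_per_component(self, small_scenario):
        graph, counts, _, _ = small_scenario
        spec = ModelSpec(family="nb", re_prior="car", outcome="visits")
        d = fit(counts, spec, McmcSettings(chains=1, iterations=200, seed=2), graph=graph)
        means = d.stacked("nu_count").mean(axis=1)
        np.testing.assert_allclose(means, 0.0, atol=1e-10)


class TestDesign:
    def test_reference_levels_dropped(self, small_scenario):
        _, counts, _, _ = small_scenario
        X, cols = build_design(counts)
        assert cols == ["intercept", "species_canine", "period_P2", "period_P3", "period_P4"]
        assert X.shape[1] == 5

    def test_single_period_subset_drops_period_term(self, small_scenario):
        _, counts, _, _ = small_scenario
        sub = counts[counts.period == "P1"]
        _, cols = build_design(sub)
        assert cols == ["intercept", "species_canine"]


def _fabricated_draws(arr):
    return PosteriorDraws(
        params={"tau_count": arr},
        tract_ids=[],
        design_columns=["intercept"],
        spec=ModelSpec(family="poisson", re_prior="exchangeable"),
        mcmc=McmcSettings(chains=arr.shape[0], iterations=arr.shape[1]),
    )


class TestDiagnostics:
    def test_iid_chains_have_unit_rhat(self):
        rng = np.random.default_rng(0)
        d = _fabricated_draws(rng.normal(size=(4, 1000)))
        out = diagnostics(d)
        assert 0.99 <= out.loc[0, "rhat"] <= 1.01
        assert out.loc[0, "ess_ratio"] > 0.5

    def test_trending_chain_flagged(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(4, 500))
        base[0] += np.linspace(0, 5, 500)
        out = diagnostics(_fabricated_draws(base))
        assert out.loc[0, "rhat"] > 1.1
        assert bool(out.loc[0, "flag"])

    def test_constant_chains_yield_nan_with_warning(self):
        d = _fabricated_draws(np.ones((4, 100)))
        with pytest.warns(UserWarning, match="zero-variance"):
            out = diagnostics(d)
        assert np.isnan(out.loc[0, "rhat"])

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="2 chains"):
            diagnostics(_fabricated_draws(np.zeros((1, 100))))


class TestPersistence:
    def test_draws_roundtrip_to_long_csv(self, small_scenario, tmp_path):
        graph, counts, _, _ = small_scenario
        spec = ModelSpec(family="poisson", re_prior="car", outcome="cancer")
        d = fit(counts, spec, McmcSettings(chains=2, iterations=100, seed=1), graph=graph)
        d.save(tmp_path / "draws.csv", tmp_path / "draws.json")
        long = pd.read_csv(tmp_path / "draws.csv")
        assert set(long.columns) == {"chain", "iter", "parameter", "value"}
        sub = long[long.parameter == "tau_count"]
        got = sub.sort_values(["chain", "iter"]).value.to_numpy().reshape(2, -1)
        np.testing.assert_allclose(got, d.params["tau_count"])
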