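import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from vetcatch.determinants import (
    compare_group_means,
    fit_logistic,
    predict_proba,
    prepare_covariates,
    roc_auc,
)
from vetcatch.synthdata import ScenarioConfig, make_grid_region, simulate_membership_logistic


@pytest.fixture(scope="module")
def region_graph():
    return make_grid_region(ScenarioConfig(seed=3))


class TestPrepareCovariates:
    def test_centering_gives_zero_means(self, region_graph):
        cov = prepare_covariates(region_graph)
        assert abs(cov.distance_km.mean()) < 1e-10
        assert abs(cov.income_k.mean()) < 1e-10

    def test_centering_constants_match_hand_means(self):
        g = make_grid_region(
            ScenarioConfig(grid_rows=2, grid_cols=3, hospital_cell=(0, 0), seed=1)
        )
        cov = prepare_covariates(g, standardize=False)
        d = g.distances_to_hospital()
        want_d = np.mean([d[t] for t in g.tract_ids])
        want_i = np.mean([g.tracts[t].avg_income for t in g.tract_ids]) / 1000.0
        assert cov.attrs["centering"]["distance_km"] == pytest.approx(want_d)
        assert cov.attrs["centering"]["income_k"] == pytest.approx(want_i)

    def test_distance_override(self, region_graph):
        override = {t: 1.0 for t in region_graph.tract_ids}
        cov = prepare_covariates(region_graph, distance_source=override)
        assert np.allclose(cov.distance_km, 0.0)  # constant centres to zero


def _cov_frame(x1, x2=None):
    df = pd.DataFrame({"distance_km": x1})
    df["income_k"] = x2 if x2 is not None else 0.0
    return df


class TestFitLogistic:
    def test_contingency_table_closed_form(self):
        # exposure x: (a,b,c,d) = (40,10,20,30): OR = 40*30/(10*20) = 6
        x = np.r_[np.ones(50), np.zeros(50)]
        y = np.r_[np.ones(40), np.zeros(10), np.ones(20), np.zeros(30)]
        fit = fit_logistic(y, _cov_frame(x), terms=("intercept", "distance"))
        assert fit.coef("distance") == pytest.approx(np.log(6.0), abs=1e-6)
        se = np.sqrt(1 / 40 + 1 / 10 + 1 / 20 + 1 / 30)
        got_se = float(fit.coefficients.set_index("term").loc["distance", "se"])
        assert got_se == pytest.approx(se, rel=1e-4)
        assert float(
            fit.coefficients.set_index("term").loc["distance", "or"]
        ) == pytest.approx(6.0, rel=1e-5)

    def test_independent_predictor_gives_unit_or(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=400)
        y = rng.integers(0, 2, size=400)
        fit = fit_logistic(y, _cov_frame(x), terms=("intercept", "distance"))
        assert abs(fit.coef("distance")) < 3 * float(
            fit.coefficients.set_index("term").loc["distance", "se"]
        )

    def test_perfect_separation_raises(self):
        x = np.r_[np.linspace(1, 2, 20), np.linspace(-2, -1, 20)]
        y = (x > 0).astype(float)
        with pytest.raises(ValueError, match="separation"):
            fit_logistic(y, _cov_frame(x), terms=("intercept", "distance"))

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_logistic(np.ones(10), _cov_frame(np.arange(10)))

    def test_sequential_deviance_decomposes_total(self):
        rng = np.random.default_rng(1)
        d = rng.normal(size=300)
        i = rng.normal(size=300)
        y = (rng.random(300) < expit(-d + 0.5 * i - 0.3 * d * i)).astype(float)
        cov = pd.DataFrame({"distance_km": d, "income_k": i})
        fit = fit_logistic(y, cov)
        drop = fit.sequential_deviance.deviance
        assert (drop > -1e-8).all()  # adding a term never hurts the MLE
        assert fit.null_deviance - drop.sum() == pytest.approx(fit.residual_deviance)

    def test_fitted_probabilities_average_to_prevalence(self):
        rng = np.random.default_rng(2)
        d = rng.normal(size=500)
        y = (rng.random(500) < expit(0.3 - d)).astype(float)
        fit = fit_logistic(y, _cov_frame(d), terms=("intercept", "distance"))
        p = predict_proba(fit, _cov_frame(d))
        assert p.mean() == pytest.approx(y.mean(), abs=1e-8)


class TestPredict:
    def test_all_zero_coefficients_give_half(self):
        y = np.r_[np.ones(20), np.zeros(20)]
        rng = np.random.default_rng(3)
        fit = fit_logistic(y, _cov_frame(rng.normal(size=40)), terms=("intercept", "distance"))
        fit.coefficients["estimate"] = 0.0
        p = predict_proba(fit, _cov_frame(np.zeros(5)))
        np.testing.assert_allclose(p, 0.5)

    def test_at_covariate_means_probability_is_inv_logit_intercept(self):
        rng = np.random.default_rng(4)
        d = rng.normal(size=200)
        y = (rng.random(200) < expit(0.8 - d)).astype(float)
        fit = fit_logistic(y, _cov_frame(d), terms=("intercept", "distance"))
        p0 = predict_proba(fit, _cov_frame(np.zeros(1)))[0]
        assert p0 == pytest.approx(expit(fit.coef("intercept")), abs=1e-10)

    def test_negative_interaction_flattens_income_slope_far_away(self, region_graph):
        # pool several membership draws: one 400-tract draw leaves the
        # interaction term underpowered
        cov1 = prepare_covariates(region_graph)
        ys = [
            simulate_membership_logistic(region_graph, 0.0, -2.0, 1.0, -0.8, seed=s)[1]
            for s in range(5)
        ]
        y = np.concatenate(ys)
        cov = pd.concat([cov1] * 5, ignore_index=True)
        cov.attrs = cov1.attrs
        fit = fit_logistic(y, cov)
        b_inc = fit.coef("income")
        b_int = fit.coef("distance:income")
        slope_near = b_inc + b_int * (-1.0)  # one SD closer than average
        slope_far = b_inc + b_int * (+1.0)
        assert b_int < 0
        assert slope_far < slope_near


class TestRocAuc:
    def test_perfect_separation_is_one(self):
        y = np.r_[np.zeros(10), np.ones(10)]
        p = np.r_[np.linspace(0, 0.4, 10), np.linspace(0.6, 1, 10)]
        assert roc_auc(p, y).auc == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, 4000)
        p = rng.random(4000)
        assert abs(roc_auc(p, y).auc - 0.5) < 0.03

    def test_equals_pairwise_oracle_exactly(self):
        rng = np.random.default_rng(7)
        n = 200
        y = rng.integers(0, 2, n)
        p = rng.choice(np.linspace(0, 1, 40), size=n)  # force ties
        auc = roc_auc(p, y).auc
        pos, neg = p[y == 1], p[y == 0]
        wins = sum((pi > ni) + 0.5 * (pi == ni) for pi in pos for ni in neg)
        assert auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, 300)
        p = rng.random(300)
        a1 = roc_auc(p, y).auc
        a2 = roc_auc(np.exp(3 * p), y).auc
        assert a1 == a2

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.2, 0.8]), np.array([1, 1]))


class TestGroupMeans:
    def test_identical_groups(self):
        out = compare_group_means(np.r_[1.0, 2, 3, 1, 2, 3], np.r_[0, 0, 0, 1, 1, 1])
        assert out["F"] == pytest.approx(0.0, abs=1e-12)
        assert out["p"] == pytest.approx(1.0, abs=1e-12)

    def test_hand_anova(self):
        out = compare_group_means(np.r_[1.0, 2, 3, 4, 5, 6], np.r_[0, 0, 0, 1, 1, 1])
        assert out["F"] == pytest.approx(13.5, abs=1e-10)
        assert out["p"] == pytest.approx(0.02138, abs=1e-4)
        assert out["means"] == {"0": 2.0, "1": 5.0}

    def test_f_equals_t_squared(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1, 25)
        from scipy import stats

        out = compare_group_means(np.r_[a, b], np.r_[np.zeros(20), np.ones(25)])
        t = stats.ttest_ind(a, b).statistic
        assert out["F"] == pytest.approx(t**2, rel=1e-10)

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            compare_group_means(np.r_[1.0, 2, 3], np.r_[0, 1, 1])


class TestLogisticLawRecovery:
    def test_signs_and_auc_ordering(self, region_graph):
        ids, y, p_true = simulate_membership_logistic(
            region_graph, 0.0, -2.0, 1.0, -0.8, seed=10
        )
        cov = prepare_covariates(region_graph)
        fit_d = fit_logistic(y, cov, terms=("intercept", "distance"))
        fit_full = fit_logistic(y, cov)
        assert fit_full.coef("distance") < 0
        assert fit_full.coef("income") > 0
        assert fit_full.coef("distance:income") < 0
        auc_d = roc_auc(predict_proba(fit_d, cov), y).auc
        auc_full = roc_auc(predict_proba(fit_full, cov), y).auc
        assert auc_full >= auc_d
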