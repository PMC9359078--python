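import numpy as np
import pandas as pd
import pytest

from vetcatch.catchment import (
    CatchmentArea,
    concordance,
    coverage,
    delineate,
    exceedance,
    per_period_cas,
    round1,
    split_primary_secondary,
)
from vetcatch.region import Tract, TractGraph

from conftest import fake_draws


class TestExceedance:
    def test_all_positive_draws(self):
        d = fake_draws(np.ones((10, 2)), ["a", "b"])
        q = exceedance(d)
        assert q.q == {"a": 1.0, "b": 1.0}

    def test_direct_count(self):
        d = fake_draws(np.array([[-1.0], [1.0], [1.0], [1.0]]), ["a"])
        assert exceedance(d).q["a"] == 0.75

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(1)
        nu = rng.normal(0, 1, size=(500, 30))
        ids = [f"t{i}" for i in range(30)]
        q = exceedance(fake_draws(nu, ids))
        for k, t in enumerate(ids):
            count = sum(1 for s in range(500) if nu[s, k] > 0)
            assert q.q[t] == count / 500

    def test_missing_effect_errors(self):
        d = fake_draws(np.ones((5, 1)), ["a"])
        with pytest.raises(ValueError, match="nu_zero"):
            exceedance(d, effect="zero_re")


class TestDelineate:
    def q(self, values):
        from vetcatch.catchment import ExceedanceResult

        return ExceedanceResult({f"t{i}": v for i, v in enumerate(values)}, 100)

    def test_closed_threshold(self):
        members = delineate(self.q([0.95, 0.90, 0.89]), 0.90)
        assert members == {"t0", "t1"}

    def test_monotone_nesting(self):
        rng = np.random.default_rng(2)
        q = self.q(rng.random(200))
        prev = None
        for thr in (0.95, 0.90, 0.85, 0.80):
            members = delineate(q, thr)
            if prev is not None:
                assert prev <= members
            prev = members

    def test_threshold_domain(self):
        with pytest.raises(ValueError):
            delineate(self.q([0.5]), 1.0)


class TestPrimarySecondary:
    def test_single_block_containing_hospital(self, grid3x3_queen):
        hosp = grid3x3_queen.hospital_tract()
        members = set(grid3x3_queen.tract_ids)
        primary, secondary = split_primary_secondary(members, grid3x3_queen, hosp)
        assert primary == members and secondary == set()

    def test_detached_member_is_secondary(self, grid10x10_queen):
        hosp = grid10x10_queen.hospital_tract()
        members = {hosp, "g0-1", "g9-9"}
        primary, secondary = split_primary_secondary(members, grid10x10_queen, hosp)
        assert "g9-9" in secondary
        assert hosp in primary

    def test_random_memberships_match_component_oracle(self, grid10x10_queen):
        from test_region import _bfs_components

        rng = np.random.default_rng(4)
        hosp = grid10x10_queen.hospital_tract()
        for _ in range(10):
            members = {t for t in grid10x10_queen.tract_ids if rng.random() < 0.35}
            members.add(hosp)
            primary, secondary = split_primary_secondary(members, grid10x10_queen, hosp)
            comps = _bfs_components(grid10x10_queen.edges, members)
            want = next(c for c in comps if hosp in c)
            assert primary == want
            assert secondary == members - want

    def test_empty_members_warns(self, grid3x3_queen):
        primary, secondary = split_primary_secondary(
            set(), grid3x3_queen, grid3x3_queen.hospital_tract()
        )
        assert primary == set() == secondary


def _universe(n):
    return [f"t{i}" for i in range(n)]


class TestCoverage:
    def toy(self):
        tracts = {
            t: Tract(t, (0.0, float(i)), 10, 1.0)
            for i, t in enumerate(["t0", "t1", "t2"])
        }
        graph = TractGraph(tracts, {("t0", "t1"), ("t1", "t2")})
        counts = pd.DataFrame(
            {
                "tract_id": ["t0", "t1", "t2"],
                "species": "canine",
                "period": "P1",
                "y_visits": [5, 3, 2],
            }
        )
        return graph, counts

    def test_full_membership_is_100pct(self):
        graph, counts = self.toy()
        ca = CatchmentArea(0.9, {"t0", "t1", "t2"})
        cov = coverage(ca, counts, graph)
        assert cov["pct_records_in_ca"] == 100.0
        assert cov["pct_tracts_in_ca"] == 100.0

    def test_hand_computed_toy_shares(self):
        graph, counts = self.toy()
        cov = coverage(CatchmentArea(0.9, {"t0"}), counts, graph)
        assert cov["pct_records_in_ca"] == 50.0
        assert cov["pct_tracts_in_ca"] == 33.3

    def test_study_area_tract_share(self):
        # 936 members of 2,707 tracts -> 34.6% of the study area
        ids = _universe(2707)
        tracts = {t: Tract(t, (0.0, 0.0), 1, 1.0) for t in ids}
        graph = TractGraph(tracts, set())
        counts = pd.DataFrame({"tract_id": ids, "y_cancer": 1})
        ca = CatchmentArea(0.9, set(ids[:936]), outcome="cancer")
        assert coverage(ca, counts, graph)["pct_tracts_in_ca"] == 34.6


class TestConcordance:
    def test_identical_cas(self):
        ids = _universe(10)
        ca = CatchmentArea(0.9, set(ids[:4]))
        out = concordance(ca, CatchmentArea(0.9, set(ids[:4])), ids)
        assert out["pct_agree"] == 100.0
        assert out["only_a"] == set() == out["only_b"]

    def test_study_counts_reproduce_printed_concordance(self):
        # 2,707 tracts; 54 only in the cancer CA, 182 only in the visits CA
        ids = _universe(2707)
        shared = set(ids[:882])
        ca_cancer = CatchmentArea(0.9, shared | set(ids[882:936]), outcome="cancer")
        ca_visits = CatchmentArea(0.9, shared | set(ids[1000:1182]), outcome="visits")
        out = concordance(ca_cancer, ca_visits, ids)
        assert out["n_agree"] == 2471
        assert out["pct_agree"] == 91.3
        assert out["pct_only_a"] == 2.0
        assert out["pct_only_b"] == 6.7

    def test_complement_cas_agree_nowhere(self):
        ids = _universe(10)
        a = CatchmentArea(0.9, set(ids[:5]))
        b = CatchmentArea(0.9, set(ids[5:]))
        assert concordance(a, b, ids)["pct_agree"] == 0.0

    def test_symmetry(self):
        ids = _universe(20)
        a = CatchmentArea(0.9, set(ids[:8]))
        b = CatchmentArea(0.9, set(ids[4:12]))
        ab = concordance(a, b, ids)
        ba = concordance(b, a, ids)
        assert ab["pct_agree"] == ba["pct_agree"]
        assert ab["only_a"] == ba["only_b"]
        assert ab["only_b"] == ba["only_a"]

    def test_universe_mismatch(self):
        a = CatchmentArea(0.9, {"zz"})
        with pytest.raises(ValueError, match="universe"):
            concordance(a, CatchmentArea(0.9, set()), _universe(3))


class TestRounding:
    @pytest.mark.parametrize(
        "x, want", [(34.649, 34.6), (91.25, 91.3), (2.04, 2.0), (6.7234, 6.7)]
    )
    def test_half_up_one_decimal(self, x, want):
        assert round1(x) == want


class TestPerPeriod:
    def test_replicated_periods_give_identical_cas(self, small_scenario):
        from vetcatch.registry import DEFAULT_PERIODS
        from vetcatch.spatial_model import McmcSettings, ModelSpec

        graph, counts, _, cfg = small_scenario
        # tile one period's counts across all four: every refit sees the same data
        p1 = counts[counts.period == "P1"]
        tiled = []
        for label in DEFAULT_PERIODS.labels:
            tiled.append(p1.assign(period=label))
        tiled = pd.concat(tiled, ignore_index=True)
        spec = ModelSpec(family="poisson", re_prior="car", outcome="visits")
        cas, combined, conc = per_period_cas(
            tiled, spec, McmcSettings(chains=1, iterations=300, seed=9),
            DEFAULT_PERIODS, graph,
        )
        memberships = [ca.members for ca in cas]
        assert all(m == memberships[0] for m in memberships)
        assert combined.members == memberships[0]
        assert (conc.pct_agree == 100.0).all()

    def test_combined_is_intersection(self, small_scenario):
        from vetcatch.registry import DEFAULT_PERIODS
        from vetcatch.spatial_model import McmcSettings, ModelSpec

        graph, counts, _, _ = small_scenario
        spec = ModelSpec(family="poisson", re_prior="car", outcome="visits")
        cas, combined, conc = per_period_cas(
            counts, spec, McmcSettings(chains=1, iterations=300, seed=9),
            DEFAULT_PERIODS, graph,
        )
        for ca in cas:
            assert combined.members <= ca.members
        assert ((conc.pct_agree >= 0) & (conc.pct_agree <= 100)).all()
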