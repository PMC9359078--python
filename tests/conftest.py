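import numpy as np
import pytest
from shapely.geometry import Polygon

from vetcatch import registry, synthdata
from vetcatch.region import Tract, TractGraph, build_adjacency


def square(x, y, size=1.0):
    return Polygon([(x, y), (x + size, y), (x + size, y + size), (x, y + size)])


def grid_tracts(rows, cols, size=0.1, households=100, income=80_000.0):
    """Unit-grid tract polygons in degree space for adjacency tests."""
    tracts = []
    for r in range(rows):
        for c in range(cols):
            tracts.append(
                Tract(
                    tract_id=f"g{r}-{c}",
                    centroid=((c + 0.5) * size, (r + 0.5) * size),
                    households=households,
                    avg_income=income,
                    polygon=square(c * size, r * size, size),
                )
            )
    return tracts


@pytest.fixture
def grid3x3_queen():
    return build_adjacency(grid_tracts(3, 3), rule="queen", hospital_point=(0.15, 0.15))


@pytest.fixture
def grid10x10_queen():
    return build_adjacency(grid_tracts(10, 10), rule="queen", hospital_point=(0.5, 0.5))


@pytest.fixture(scope="session")
def small_scenario():
    """6x6 default-family scenario with expected counts filled (fast fits)."""
    cfg = synthdata.ScenarioConfig(grid_rows=6, grid_cols=6, hospital_cell=(3, 3), seed=7)
    graph, counts, truth = synthdata.make_scenario(cfg)
    return graph, registry.expected_counts(counts), truth, cfg


@pytest.fixture(scope="session")
def default_scenario():
    """The 20x20 study-scale scenario (shared by the slower recovery tests)."""
    cfg = synthdata.ScenarioConfig(seed=1)
    graph, counts, truth = synthdata.make_scenario(cfg)
    return graph, registry.expected_counts(counts), truth, cfg


def fake_draws(nu_matrix, tract_ids, extra=None):
    """PosteriorDraws carrying a given (S, T) nu_count matrix as one chain."""
    from vetcatch.spatial_model import McmcSettings, ModelSpec, PosteriorDraws

    params = {"nu_count": np.asarray(nu_matrix)[None, ...]}
    if extra:
        params.update({k: np.asarray(v)[None, ...] for k, v in extra.items()})
    return PosteriorDraws(
        params=params,
        tract_ids=list(tract_ids),
        design_columns=["intercept"],
        spec=ModelSpec(family="poisson", re_prior="exchangeable"),
        mcmc=McmcSettings(chains=1, iterations=len(nu_matrix)),
    )
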