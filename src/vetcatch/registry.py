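"""Registry records -> deduplicated, stratified counts with SIR-style offsets.

Raw hospital visit rows (one per animal visit) are collapsed to at most one
record per animal-year; an animal-year with any cancer diagnosis counts as
one cancer record. Counts are then laid out on the full
tract x species x period grid, populations estimated from household counts,
and expected counts computed from the global rate so that the observed and
expected grand totals match (a standardized-incidence-ratio offset).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .region import TractGraph

log = logging.getLogger(__name__)

SPECIES = ("canine", "feline")

#: animals per household (California state averages from AVMA ownership surveys)
ANIMALS_PER_HOUSEHOLD = {"canine": 1.6, "feline": 1.7}


@dataclass(frozen=True)
class VisitRecord:
    animal_id: str
    species: str
    year: int
    cancer: bool
    tract_id: str

    def __post_init__(self):
        if self.species not in SPECIES:
            raise ValueError(f"species must be one of {SPECIES}, got {self.species!r}")


@dataclass(frozen=True)
class PeriodScheme:
    """Ordered, contiguous, non-overlapping (label, start_year, end_year) bins."""

    periods: tuple[tuple[str, int, int], ...]

    def __post_init__(self):
        prev_end = None
        for label, start, end in self.periods:
            if start > end:
                raise ValueError(f"period {label}: start > end")
            if prev_end is not None and start != prev_end + 1:
                raise ValueError(f"period {label}: scheme not contiguous")
            prev_end = end

    @property
    def labels(self) -> list[str]:
        return [p[0] for p in self.periods]

    @property
    def window(self) -> tuple[int, int]:
        return self.periods[0][1], self.periods[-1][2]


#: the four five-year study periods
DEFAULT_PERIODS = PeriodScheme(
    (
        ("P1", 2000, 2004),
        ("P2", 2005, 2009),
        ("P3", 2010, 2014),
        ("P4", 2015, 2019),
    )
)


def assign_period(year: int, scheme: PeriodScheme = DEFAULT_PERIODS) -> str:
    for label, start, end in scheme.periods:
        if start <= year <= end:
            return label
    raise ValueError(f"year {year} outside the study window {scheme.window}")


def deduplicate(records: list[VisitRecord]) -> list[VisitRecord]:
    """At most one record per animal-year; cancer wins over plain visits.

    The retained row is the first cancer record of that animal-year in input
    order, or the first record overall when none is a cancer record; its
    tract_id is kept. Conflicting species for one animal_id is an error.
    """
    species_seen: dict[str, str] = {}
    chosen: dict[tuple[str, int], VisitRecord] = {}
    order: list[tuple[str, int]] = []
    conflicts: set[str] = set()
    for rec in records:
        prev_sp = species_seen.setdefault(rec.animal_id, rec.species)
        if prev_sp != rec.species:
            conflicts.add(rec.animal_id)
        key = (rec.animal_id, rec.year)
        cur = chosen.get(key)
        if cur is None:
            chosen[key] = rec
            order.append(key)
        elif rec.cancer and not cur.cancer:
            chosen[key] = rec
        elif cur.tract_id != rec.tract_id and rec.cancer == cur.cancer:
            log.warning(
                "animal %s year %d has records in several tracts; keeping %s",
                rec.animal_id,
                rec.year,
                cur.tract_id,
            )
    if conflicts:
        raise ValueError(f"conflicting species for animal ids: {sorted(conflicts)}")
    return [chosen[k] for k in order]


def estimate_population(
    households: int, species: str, rates: dict[str, float] | None = None
) -> float:
    """Animals in a tract: households x species rate (1.6 dogs / 1.7 cats)."""
    if households < 0:
        raise ValueError("households must be >= 0")
    rates = rates or ANIMALS_PER_HOUSEHOLD
    return households * rates[species]


def stratify(
    records: list[VisitRecord],
    graph: TractGraph,
    scheme: PeriodScheme = DEFAULT_PERIODS,
    rates: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Stratified counts on the full tract x species x period grid.

    Returns a DataFrame with columns tract_id, species, period, y_visits,
    y_cancer, population (strata with no records get explicit zeros).
    ``y_visits`` counts every deduplicated record; ``y_cancer`` the
    cancer-flagged subset.
    """
    unknown = [r for r in records if r.tract_id not in graph.tracts]
    if unknown:
        raise ValueError(
            f"{len(unknown)} records reference tract ids absent from the graph "
            f"(e.g. {unknown[0].tract_id!r})"
        )
    tract_ids = graph.tract_ids
    grid = pd.MultiIndex.from_product(
        [tract_ids, list(SPECIES), scheme.labels],
        names=["tract_id", "species", "period"],
    )
    counts = pd.DataFrame(index=grid).assign(y_visits=0, y_cancer=0)
    if records:
        rows = pd.DataFrame(
            {
                "tract_id": [r.tract_id for r in records],
                "species": [r.species for r in records],
                "period": [assign_period(r.year, scheme) for r in records],
                "cancer": [int(r.cancer) for r in records],
            }
        )
        agg = rows.groupby(["tract_id", "species", "period"]).agg(
            y_visits=("cancer", "size"), y_cancer=("cancer", "sum")
        )
        counts.loc[agg.index, ["y_visits", "y_cancer"]] = agg
    counts = counts.reset_index()
    hh = {tid: graph.tracts[tid].households for tid in tract_ids}
    counts["population"] = [
        estimate_population(hh[t], s, rates)
        for t, s in zip(counts["tract_id"], counts["species"])
    ]
    return counts


def expected_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Fill e_visits / e_cancer: global rate (total y / total population) x population.

    The global-rate offset makes the expected counts sum to the observed
    totals, so the relative risk R in mu = e * R is centred at 1.
    """
    if "population" not in counts:
        raise ValueError("population column required")
    out = counts.copy()
    pop_total = float(out["population"].sum())
    if pop_total <= 0:
        raise ValueError("total population is zero")
    for col in ("visits", "cancer"):
        y_total = float(out[f"y_{col}"].sum())
        out[f"e_{col}"] = (y_total / pop_total) * out["population"]
        assert np.isclose(out[f"e_{col}"].sum(), y_total, rtol=1e-9)
    return out


def read_records_csv(path) -> list[VisitRecord]:
    """Records CSV: header animal_id,species,year,cancer,tract_id (cancer in {0,1})."""
    df = pd.read_csv(path, dtype={"animal_id": str, "tract_id": str})
    bad = df.index[~df["species"].isin(SPECIES)]
    if len(bad):
        raise ValueError(f"invalid species on lines {list(bad[:5] + 2)}")
    return [
        VisitRecord(r.animal_id, r.species, int(r.year), bool(int(r.cancer)), r.tract_id)
        for r in df.itertuples(index=False)
    ]


def write_records_csv(records: list[VisitRecord], path) -> None:
    pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in records],
            "species": [r.species for r in records],
            "year": [r.year for r in records],
            "cancer": [int(r.cancer) for r in records],
            "tract_id": [r.tract_id for r in records],
        }
    ).to_csv(path, index=False)
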