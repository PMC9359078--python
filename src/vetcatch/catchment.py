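"""Catchment-area delineation from posterior tract effects.

A tract belongs to the catchment area (CA) when its exceedance probability
q_i = Pr(RR_i > 1 | data) = Pr(nu_i > 0 | data) reaches the threshold
(0.90 by convention in disease mapping; 0.80-0.95 explored). Members are
split into a primary area (the connected block containing the hospital
tract) and a secondary area (members with no geographic connection to it).
Coverage and concordance summaries express how much of the registry the CA
captures and how two delineations agree tract-by-tract.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .region import TractGraph, connected_components, haversine_km
from .registry import PeriodScheme
from .spatial_model import McmcSettings, ModelSpec, PosteriorDraws, Priors, fit

log = logging.getLogger(__name__)


def round1(x: float) -> float:
    """Round half-up to 1 decimal (reporting convention for percentages)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class ExceedanceResult:
    q: dict[str, float]  # per-tract Pr(nu_i > 0)
    n_draws: int


@dataclass
class CatchmentArea:
    threshold: float
    members: set[str]
    primary: set[str] = field(default_factory=set)
    secondary: set[str] = field(default_factory=set)
    outcome: str = "visits"
    period: str = "all"


def exceedance(draws: PosteriorDraws, effect: str = "count_re") -> ExceedanceResult:
    """Per-tract posterior probability that the random effect exceeds 0.

    ``effect`` selects the count-model effect (default: the count intensity
    drives case submission), the zero-model effect, or their sum.
    """
    key = {"count_re": "nu_count", "zero_re": "nu_zero", "sum": None}[effect]
    if effect == "sum":
        if "nu_zero" not in draws.params:
            raise ValueError("draws carry no zero-model tract effects")
        nu = draws.stacked("nu_count") + draws.stacked("nu_zero")
    else:
        if key not in draws.params:
            raise ValueError(f"draws carry no {key} parameters")
        nu = draws.stacked(key)
    q = (nu > 0).mean(axis=0)
    return ExceedanceResult(
        q={t: float(q[k]) for k, t in enumerate(draws.tract_ids)},
        n_draws=nu.shape[0],
    )


def delineate(q: ExceedanceResult, threshold: float) -> set[str]:
    """Members = {i : q_i >= threshold}; monotone in the threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    return {t for t, qi in q.q.items() if qi >= threshold}


def split_primary_secondary(
    members: set[str], graph: TractGraph, hospital_tract: str
) -> tuple[set[str], set[str]]:
    """Primary = connected block of members containing the hospital tract.

    If the hospital tract is not a member, the largest member component is
    primary (ties broken by proximity of the component's nearest centroid to
    the hospital). Everything else is secondary.
    """
    if hospital_tract not in graph.tracts:
        raise ValueError(f"hospital tract {hospital_tract!r} not in graph")
    if not members:
        log.warning("empty catchment membership")
        return set(), set()
    comps = connected_components(graph, set(members))
    primary = next((c for c in comps if hospital_tract in c), None)
    if primary is None:
        hp = graph.hospital_point or graph.tracts[hospital_tract].centroid

        def nearest_km(comp):
            return min(haversine_km(graph.tracts[t].centroid, hp) for t in comp)

        primary = max(comps, key=lambda c: (len(c), -nearest_km(c)))
    return set(primary), set(members) - set(primary)


def coverage(ca: CatchmentArea, counts: pd.DataFrame, graph: TractGraph) -> dict:
    """Share of records and of tracts captured by the CA (percent).

    Reported values are rounded half-up to one decimal; *_raw keys keep full
    precision.
    """
    ycol = f"y_{ca.outcome}"
    total = float(counts[ycol].sum())
    in_ca = float(counts.loc[counts["tract_id"].isin(ca.members), ycol].sum())
    pct_records = 100.0 * in_ca / total if total > 0 else 0.0
    pct_tracts = 100.0 * len(ca.members) / len(graph.tracts)
    return {
        "pct_records_in_ca": round1(pct_records),
        "pct_tracts_in_ca": round1(pct_tracts),
        "pct_records_in_ca_raw": pct_records,
        "pct_tracts_in_ca_raw": pct_tracts,
        "n_members": len(ca.members),
    }


def concordance(ca_a: CatchmentArea, ca_b: CatchmentArea, all_tracts) -> dict:
    """Tract-by-tract agreement of two in/out classifications (percent)."""
    universe = set(all_tracts)
    for ca in (ca_a, ca_b):
        extra = ca.members - universe
        if extra:
            raise ValueError(f"members outside the tract universe: {sorted(extra)[:5]}")
    only_a = ca_a.members - ca_b.members
    only_b = ca_b.members - ca_a.members
    n_total = len(universe)
    n_agree = n_total - len(only_a) - len(only_b)
    return {
        "pct_agree": round1(100.0 * n_agree / n_total),
        "pct_agree_raw": 100.0 * n_agree / n_total,
        "n_agree": n_agree,
        "n_total": n_total,
        "only_a": only_a,
        "only_b": only_b,
        "pct_only_a": round1(100.0 * len(only_a) / n_total),
        "pct_only_b": round1(100.0 * len(only_b) / n_total),
    }


def delineate_full(
    draws: PosteriorDraws,
    graph: TractGraph,
    threshold: float = 0.90,
    outcome: str | None = None,
    period: str = "all",
    effect: str = "count_re",
) -> CatchmentArea:
    """Exceedance -> threshold -> primary/secondary split, as one call."""
    q = exceedance(draws, effect)
    members = delineate(q, threshold)
    hosp = graph.hospital_tract()
    primary, secondary = (
        split_primary_secondary(members, graph, hosp) if hosp else (set(members), set())
    )
    return CatchmentArea(
        threshold=threshold,
        members=members,
        primary=primary,
        secondary=secondary,
        outcome=outcome or draws.spec.outcome,
        period=period,
    )


def per_period_cas(
    counts: pd.DataFrame,
    spec: ModelSpec,
    mcmc: McmcSettings,
    scheme: PeriodScheme,
    graph: TractGraph,
    threshold: float = 0.90,
    priors: Priors | None = None,
):
    """One fit + delineation per period, plus the intersection ("combined").

    Each period is refit on its subset of the grid (species remains a fixed
    effect; the period term drops out). Returns (list of CatchmentArea,
    combined CatchmentArea, pairwise concordance DataFrame).
    """
    cas = []
    for label in scheme.labels:
        sub = counts[counts["period"] == label]
        if sub[f"y_{spec.outcome}"].sum() == 0:
            log.warning("period %s has no records: empty CA", label)
            cas.append(CatchmentArea(threshold, set(), outcome=spec.outcome, period=label))
            continue
        draws = fit(sub, spec, mcmc=mcmc, graph=graph, priors=priors)
        cas.append(delineate_full(draws, graph, threshold, period=label))
    combined_members = (
        set.intersection(*[ca.members for ca in cas]) if cas else set()
    )
    hosp = graph.hospital_tract()
    prim, sec = (
        split_primary_secondary(combined_members, graph, hosp)
        if hosp and combined_members
        else (set(), set())
    )
    combined = CatchmentArea(
        threshold, combined_members, prim, sec, outcome=spec.outcome, period="combined"
    )
    rows = []
    for i in range(len(cas)):
        for j in range(i + 1, len(cas)):
            c = concordance(cas[i], cas[j], graph.tract_ids)
            rows.append(
                {
                    "period_a": cas[i].period,
                    "period_b": cas[j].period,
                    "pct_agree": c["pct_agree"],
                }
            )
    return cas, combined, pd.DataFrame(rows)


def write_ca_csv(ca: CatchmentArea, q: ExceedanceResult, graph: TractGraph, path):
    """Per-tract CSV: tract_id, q, member, zone (primary/secondary/outside)."""
    rows = []
    for t in graph.tract_ids:
        zone = (
            "primary" if t in ca.primary else "secondary" if t in ca.secondary else "outside"
        )
        rows.append(
            {"tract_id": t, "q": q.q.get(t, np.nan), "member": int(t in ca.members), "zone": zone}
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_summary_json(summaries: dict, path):
    with open(path, "w") as fh:
        json.dump(summaries, fh, indent=1, default=str)
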