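"""End-to-end pipeline commands: simulate, prepare, fit grid, delineate,
determinants.

Each command is a plain function over library objects with an optional
output directory; the CLI and the numbered analysis scripts are thin
wrappers around these. A single seed governs every stochastic stage;
per-stage seeds are derived deterministically from it.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import catchment as ca_mod
from . import determinants as det_mod
from . import region, registry, selection, synthdata
from .spatial_model import McmcSettings, ModelSpec, fit

log = logging.getLogger(__name__)

#: study-design settings: buffer radius (km), exceedance thresholds explored
BUFFER_RADIUS_KM = 233.0
THRESHOLDS = (0.80, 0.85, 0.90, 0.95)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 (stable name hash)."""
    h = 2166136261
    for ch in stage.encode():
        h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
    return (seed * 1009 + h) % (2**31 - 1)


def cmd_simulate(config: synthdata.ScenarioConfig, outdir, write_records=False):
    """Write a synthetic scenario: GeoJSON geography, stratified counts CSV,
    ground-truth JSON and (optionally) raw records CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    graph, counts, truth = synthdata.make_scenario(config)
    counts = registry.expected_counts(counts)
    region.write_geojson(graph, outdir / "tracts.geojson")
    counts.to_csv(outdir / "stratified_counts.csv", index=False)
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth.to_json_dict(), fh)
    if write_records:
        records = synthdata.expand_to_records(
            counts, config.scheme, stage_seed(config.seed, "records")
        )
        registry.write_records_csv(records, outdir / "records.csv")
    log.info(
        "scenario: %d tracts, %d strata, %d visits, %d cancer records",
        len(graph.tracts), len(counts),
        counts["y_visits"].sum(), counts["y_cancer"].sum(),
    )
    return graph, counts, truth


def cmd_prepare(records, graph, radius_km=BUFFER_RADIUS_KM, scheme=None, outdir=None):
    """Buffer filter -> deduplicate -> stratify -> expected-count offsets."""
    scheme = scheme or registry.DEFAULT_PERIODS
    buffered = region.filter_buffer(graph, radius_km)
    in_buffer = [r for r in records if r.tract_id in buffered.tracts]
    if records:
        log.info(
            "buffer subset: %d of %d records (%.1f%%)",
            len(in_buffer), len(records), 100.0 * len(in_buffer) / len(records),
        )
    deduped = registry.deduplicate(in_buffer)
    log.info("deduplication: %d of %d records retained", len(deduped), len(in_buffer))
    counts = registry.expected_counts(registry.stratify(deduped, buffered, scheme))
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        counts.to_csv(outdir / "stratified_counts.csv", index=False)
    return buffered, counts


def cmd_fit_grid(
    counts,
    graph,
    outcome="visits",
    families=("poisson", "zip", "nb", "zinb", "cmp", "zicmp"),
    re_priors=("exchangeable", "car"),
    mcmc: McmcSettings | None = None,
    outdir=None,
    loo_thin: int = 1,
):
    """Fit the family x prior grid for one outcome and rank by PSIS-LOO.

    Individual model failures are logged and the grid continues. Returns
    (comparison DataFrame, dict spec -> draws); the best model is row 0.
    """
    mcmc = mcmc or McmcSettings()
    results, draws_by_spec = [], {}
    for family in families:
        for prior in re_priors:
            spec = ModelSpec(family=family, re_prior=prior, outcome=outcome)
            try:
                draws = fit(counts, spec, mcmc=mcmc, graph=graph)
                ll = selection.pointwise_loglik(draws, counts, spec, thin=loo_thin)
                results.append((spec, selection.psis_loo(ll)))
                draws_by_spec[(family, prior)] = draws
            except Exception:
                log.exception("model %s+%s failed; continuing grid", family, prior)
    table = selection.compare(results)
    table.insert(0, "best", [i == 0 for i in range(len(table))])
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / f"model_comparison_{outcome}.csv", index=False)
    return table, draws_by_spec


def cmd_delineate(draws_by_outcome: dict, graph, counts, thresholds=THRESHOLDS, outdir=None):
    """Exceedance -> CA per threshold and outcome -> coverage + concordance.

    ``draws_by_outcome`` maps outcome name -> PosteriorDraws of the selected
    model for that outcome. Returns (dict (outcome, threshold) -> CatchmentArea,
    summary dict).
    """
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    cas, summary = {}, {"thresholds": {}, "concordance": {}}
    qs = {}
    for outcome, draws in draws_by_outcome.items():
        qs[outcome] = ca_mod.exceedance(draws)
        for thr in thresholds:
            members = ca_mod.delineate(qs[outcome], thr)
            hosp = graph.hospital_tract()
            prim, sec = ca_mod.split_primary_secondary(members, graph, hosp)
            ca = ca_mod.CatchmentArea(thr, members, prim, sec, outcome=outcome)
            cas[(outcome, thr)] = ca
            cov = ca_mod.coverage(ca, counts, graph)
            summary["thresholds"].setdefault(outcome, {})[str(thr)] = cov
            if outdir is not None and thr == 0.90:
                ca_mod.write_ca_csv(ca, qs[outcome], graph, outdir / f"ca_{outcome}.csv")
                region.write_geojson(
                    graph,
                    outdir / f"ca_{outcome}.geojson",
                    extra_properties={
                        t: {
                            "q": qs[outcome].q[t],
                            "member": int(t in ca.members),
                            "zone": "primary" if t in ca.primary
                            else "secondary" if t in ca.secondary else "outside",
                        }
                        for t in graph.tract_ids
                    },
                )
    outcomes = list(draws_by_outcome)
    if len(outcomes) == 2:
        a, b = outcomes
        conc = ca_mod.concordance(cas[(a, 0.90)], cas[(b, 0.90)], graph.tract_ids)
        summary["concordance"][f"{a}_vs_{b}"] = {
            k: (sorted(v) if isinstance(v, set) else v) for k, v in conc.items()
        }
    if outdir is not None:
        ca_mod.write_summary_json(summary, outdir / "ca_summary.json")
    return cas, summary


def cmd_determinants(graph, ca, outdir=None, standardize=True):
    """Nested logistic fits (distance; +income; +interaction), ROC per fit,
    and the member vs non-member income contrast."""
    cov = det_mod.prepare_covariates(graph, standardize=standardize)
    y = cov["tract_id"].isin(ca.members).to_numpy(int)
    fits, rocs = {}, {}
    nested = [
        ("distance", ("intercept", "distance")),
        ("distance+income", ("intercept", "distance", "income")),
        ("full", ("intercept", "distance", "income", "distance:income")),
    ]
    for name, terms in nested:
        f = det_mod.fit_logistic(y, cov, terms)
        p = det_mod.predict_proba(f, cov)
        fits[name] = f
        rocs[name] = det_mod.roc_auc(p, y)
    income = np.array([graph.tracts[t].avg_income for t in cov["tract_id"]])
    groups = det_mod.compare_group_means(income, y)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        full = fits["full"]
        tab = full.coefficients.merge(
            full.sequential_deviance, on="term", how="left"
        )
        tab["auc_at_this_step"] = [np.nan] + [
            rocs[n].auc for n, _ in nested
        ]
        tab.to_csv(outdir / f"determinants_{ca.outcome}.csv", index=False)
        pd.DataFrame(
            {
                "fpr": rocs["full"].fpr,
                "tpr": rocs["full"].tpr,
                "threshold": rocs["full"].thresholds,
            }
        ).to_csv(outdir / f"roc_{ca.outcome}.csv", index=False)
    return fits, rocs, groups
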