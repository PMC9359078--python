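"""Determinants of catchment membership: distance x income logistic model.

The binary outcome is a tract's inclusion in the catchment area. Predictors
are distance to the hospital (km) and average household income (thousands
of USD), centred on their means and by default also scaled to unit SD;
terms enter in the order distance, income, distance x income, and the fit
reports sequential deviance contributions, odds ratios with Wald 95% CIs,
ROC/AUC accuracy, and group-mean contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit
from sklearn.metrics import roc_curve

from .region import TractGraph

TERMS = ("intercept", "distance", "income", "distance:income")


@dataclass
class DeterminantFit:
    coefficients: pd.DataFrame  # term, estimate, se, or, ci_low, ci_high
    sequential_deviance: pd.DataFrame  # term, deviance drop when added
    null_deviance: float
    residual_deviance: float
    centering: dict[str, float]
    scaling: dict[str, float]
    terms: tuple[str, ...] = TERMS

    def coef(self, term: str) -> float:
        return float(
            self.coefficients.set_index("term").loc[term, "estimate"]
        )


@dataclass
class RocResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def prepare_covariates(
    graph: TractGraph,
    distance_source: dict[str, float] | None = None,
    standardize: bool = True,
) -> pd.DataFrame:
    """Per-tract centred distance (km) and income (k$) covariates.

    ``distance_source`` overrides the great-circle centroid-to-hospital
    distance (e.g. with true driving distances). Income is divided by 1,000
    before centring. Centering (and scaling, when enabled) constants are
    attached as DataFrame attrs so fits and predictions share them.
    """
    dists = distance_source or graph.distances_to_hospital()
    rows = []
    for t in graph.tract_ids:
        tr = graph.tracts[t]
        if tr.avg_income is None or not np.isfinite(tr.avg_income):
            warnings.warn(f"tract {t}: missing income, excluded")
            continue
        rows.append(
            {"tract_id": t, "distance_km": dists[t], "income_k": tr.avg_income / 1000.0}
        )
    df = pd.DataFrame(rows)
    centering = {
        "distance_km": float(df["distance_km"].mean()),
        "income_k": float(df["income_k"].mean()),
    }
    scaling = {"distance_km": 1.0, "income_k": 1.0}
    for c in ("distance_km", "income_k"):
        df[c] = df[c] - centering[c]
        if standardize:
            sd = float(df[c].std(ddof=0))
            if sd > 0:  # a constant covariate stays centred at zero
                scaling[c] = sd
                df[c] = df[c] / sd
    df.attrs["centering"] = centering
    df.attrs["scaling"] = scaling
    return df


def _design(cov: pd.DataFrame, terms) -> np.ndarray:
    cols = [np.ones(len(cov))]
    if "distance" in terms:
        cols.append(cov["distance_km"].to_numpy())
    if "income" in terms:
        cols.append(cov["income_k"].to_numpy())
    if "distance:income" in terms:
        cols.append((cov["distance_km"] * cov["income_k"]).to_numpy())
    return np.column_stack(cols)


def _glm_fit(y, X):
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                tol=1e-8, maxiter=100
            )
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning) as err:
            raise ValueError("perfect separation: logistic MLE does not exist") from err
    if np.any(np.abs(res.params) > 30):
        raise ValueError("perfect separation: logistic MLE does not exist")
    return res


def fit_logistic(y, cov: pd.DataFrame, terms: tuple[str, ...] = TERMS) -> DeterminantFit:
    """IRLS logistic fit of CA membership on the prepared covariates.

    Sequential deviance reports the drop in deviance as each term is added
    in order (distance, income, interaction), matching the convention of
    type-I analysis-of-deviance tables.
    """
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise ValueError("membership indicator is constant")
    fitted_terms = [t for t in terms if t != "intercept"]
    null = _glm_fit(y, np.ones((len(y), 1)))
    prev_dev = null.deviance
    seq = []
    res = null
    for k in range(1, len(fitted_terms) + 1):
        X = _design(cov, ["intercept"] + fitted_terms[:k])
        res = _glm_fit(y, X)
        seq.append({"term": fitted_terms[k - 1], "deviance": prev_dev - res.deviance})
        prev_dev = res.deviance
    coefs = pd.DataFrame(
        {
            "term": ["intercept"] + fitted_terms,
            "estimate": res.params,
            "se": res.bse,
        }
    )
    coefs["or"] = np.exp(coefs["estimate"])
    coefs["ci_low"] = np.exp(coefs["estimate"] - 1.96 * coefs["se"])
    coefs["ci_high"] = np.exp(coefs["estimate"] + 1.96 * coefs["se"])
    return DeterminantFit(
        coefficients=coefs,
        sequential_deviance=pd.DataFrame(seq),
        null_deviance=float(null.deviance),
        residual_deviance=float(res.deviance),
        centering=cov.attrs.get("centering", {}),
        scaling=cov.attrs.get("scaling", {}),
        terms=tuple(["intercept"] + fitted_terms),
    )


def predict_proba(fit: DeterminantFit, cov: pd.DataFrame) -> np.ndarray:
    """Inclusion probabilities for covariates transformed like the fit's.

    Emits a warning when the inputs do not look centred (their mean is far
    from zero), which usually means raw rather than prepared covariates.
    """
    for c in ("distance_km", "income_k"):
        if c in cov and len(cov) > 3 and abs(cov[c].mean()) > 2.0 * (cov[c].std() + 1e-9):
            warnings.warn(f"covariate {c} does not look centred; use prepare_covariates")
    X = _design(cov, fit.terms)
    beta = fit.coefficients["estimate"].to_numpy()
    return expit(X @ beta)


def profile_curve(
    fit: DeterminantFit, income_grid: np.ndarray, distance_levels: list[float]
) -> pd.DataFrame:
    """Inclusion-probability curves over income at fixed distance levels
    (all on the transformed, centred scale)."""
    rows = []
    for d in distance_levels:
        cov = pd.DataFrame(
            {"distance_km": np.full(len(income_grid), d), "income_k": income_grid}
        )
        p = predict_proba(fit, cov)
        rows.append(pd.DataFrame({"distance": d, "income": income_grid, "p": p}))
    return pd.concat(rows, ignore_index=True)


def roc_auc(probabilities, y) -> RocResult:
    """ROC curve and AUC by the Mann-Whitney rank statistic (ties half-credit)."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(y, dtype=int)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(p)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, thr = roc_curve(y, p)
    return RocResult(thresholds=thr, tpr=tpr, fpr=fpr, auc=float(auc))


def compare_group_means(values, membership) -> dict:
    """One-way ANOVA contrast of a tract covariate between CA members and
    non-members (two groups => F = t^2)."""
    v = np.asarray(values, dtype=float)
    g = np.asarray(membership)
    groups = [v[g == lev] for lev in np.unique(g)]
    if len(groups) < 2 or any(len(x) < 2 for x in groups):
        raise ValueError("need >= 2 observations in each of >= 2 groups")
    f, pval = stats.f_oneway(*groups)
    return {
        "means": {str(lev): float(v[g == lev].mean()) for lev in np.unique(g)},
        "F": float(f),
        "p": float(pval),
    }
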