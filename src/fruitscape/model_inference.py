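"""Multivariate inference: category prescreen, BMA, hierarchical partitioning.

To limit multicollinearity, each multi-member environmental category
(temperature, precipitation, seasonality, productivity) first contributes at
most one predictor — the member with the best univariate fit, provided the
category holds at least one spatially-corrected significant member. The
surviving candidates enter an exhaustive BIC-based Bayesian model averaging
over all binomial GLMs; the top three posterior models and their union
("combined" model) are reported. Hierarchical partitioning then splits the
combined model's goodness of fit into independent and joint contributions
per predictor by averaging improvements over the full subset hierarchy.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

from .cell_metrics import ModelFrame
from .glm_core import fit_binomial_glm
from .spatial_stats import modified_ttest

__all__ = [
    "DEFAULT_CATEGORIES",
    "BMAResult",
    "HierPartResult",
    "prescreen_categories",
    "bma_enumerate",
    "hierarchical_partition",
]

log = logging.getLogger(__name__)

#: predictor categories; multi-member categories contribute one member each
DEFAULT_CATEGORIES = {
    "temperature": ["MAT", "MTCQ"],
    "precipitation": ["MPWQ", "AI"],
    "seasonality": ["TSN", "PSN"],
    "productivity": ["AET", "NPP", "GPP"],
    "height": ["height"],
    "age": ["age"],
}


def prescreen_categories(
    univariate_table: pd.DataFrame,
    category_map: dict[str, list] | None = None,
    alpha: float = 0.05,
) -> list[str]:
    """Reduce the candidate set to one predictor per category.

    For every multi-member category the member with the highest univariate
    McFadden R^2 is chosen, unless no member reaches corrected significance
    (p < alpha), in which case the whole category is dropped. Singleton
    categories pass through. The univariate table must be indexed by
    predictor with ``mcfadden_r2`` and ``p_corrected`` columns.
    """
    category_map = category_map or DEFAULT_CATEGORIES
    selected: list[str] = []
    for cat, members in category_map.items():
        present = [m for m in members if m in univariate_table.index]
        if not present:
            continue
        if len(present) == 1:
            selected.append(present[0])
            continue
        sub = univariate_table.loc[present]
        if not (sub["p_corrected"] < alpha).any():
            log.info("category %r dropped: no member significant at %.3g", cat, alpha)
            continue
        selected.append(sub["mcfadden_r2"].idxmax())
    if not selected:
        raise ValueError("prescreen selected no predictors; nothing to model")
    log.info("prescreen selected: %s", selected)
    return selected


@dataclass
class BMAResult:
    """Exhaustive BIC-weighted model averaging over binomial GLMs."""

    models: pd.DataFrame          # one row per retained model, posterior-ranked
    top3: pd.DataFrame
    combined_predictors: list
    combined: object              # GLMFit for the union of top-3 predictor sets
    inclusion_probability: dict
    candidates: list = field(default_factory=list)


def _fit_subset(frame: ModelFrame, subset: tuple):
    X = frame.subset(list(subset)) if subset else np.empty((len(frame.successes), 0))
    return fit_binomial_glm(X, frame.successes, frame.totals,
                            names=["intercept", *subset])


def bma_enumerate(frame: ModelFrame, candidates: list,
                  occam_odds: float = 20.0) -> BMAResult:
    """Fit all 2^k binomial GLMs and weight them by exp(-BIC/2).

    Models whose posterior odds against the best model exceed ``occam_odds``
    are discarded (Occam's window) before renormalization. The corrected
    p-value per model is the modified t-test between observed and fitted
    proportions.
    """
    if len(candidates) > 12:
        raise ValueError("exhaustive enumeration limited to 12 candidates")
    obs = frame.proportions
    rows = []
    fits = {}
    for k in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, k):
            fit = _fit_subset(frame, subset)
            fits[subset] = fit
            rows.append({"predictors": subset, "k": k, "bic": fit.bic,
                         "aic": fit.aic, "mcfadden_r2": fit.mcfadden_r2,
                         "loglik": fit.loglik})
    df = pd.DataFrame(rows)
    dbic = df["bic"] - df["bic"].min()
    raw = np.exp(-0.5 * dbic)
    keep = (raw.max() / raw) <= occam_odds
    df = df[keep].copy()
    df["posterior"] = raw[keep] / raw[keep].sum()
    df = df.sort_values("posterior", ascending=False).reset_index(drop=True)

    incl = {
        c: float(df.loc[[c in s for s in df["predictors"]], "posterior"].sum())
        for c in candidates
    }

    top3 = df.head(3).copy()
    pvals = []
    for s in top3["predictors"]:
        fit = fits[s]
        if s:
            mt = modified_ttest(obs, fit.fitted, frame.centroids)
            pvals.append(mt.p)
        else:
            pvals.append(np.nan)
    top3["p_corrected"] = pvals

    union: list[str] = [c for c in candidates
                        if any(c in s for s in top3["predictors"])]
    combined = fits.get(tuple(union)) or _fit_subset(frame, tuple(union))
    return BMAResult(models=df, top3=top3, combined_predictors=union,
                     combined=combined, inclusion_probability=incl,
                     candidates=list(candidates))


@dataclass
class HierPartResult:
    """Per-predictor independent and joint contributions (same GOF units)."""

    table: pd.DataFrame          # index predictor; independent, joint, total
    gof_name: str
    gof_full: float

    @property
    def independent(self) -> dict:
        return self.table["independent"].to_dict()


def _gof_values(frame: ModelFrame, predictors: list, gof: str) -> dict:
    obs = frame.proportions
    vals = {}
    for k in range(len(predictors) + 1):
        for subset in itertools.combinations(predictors, k):
            fit = _fit_subset(frame, subset)
            if gof == "rms":
                vals[frozenset(subset)] = -float(
                    np.sqrt(np.mean((obs - fit.fitted) ** 2))
                )
            elif gof == "loglik":
                vals[frozenset(subset)] = fit.loglik
            else:
                raise ValueError(f"unknown gof {gof!r}")
    null = vals[frozenset()]
    return {s: v - null for s, v in vals.items()}  # improvement over null


def hierarchical_partition(frame: ModelFrame, predictors: list,
                           gof: str = "rms") -> HierPartResult:
    """Chevan–Sutherland hierarchical partitioning over all 2^k subsets.

    Goodness of fit defaults to the reduction in root-mean-square error
    between observed and fitted proportions relative to the null model, so
    contributions are in RMS-improvement units and positive for useful
    predictors. The independent contribution of predictor j averages its
    marginal improvement over every subset not containing j, level by level;
    the joint contribution is the single-predictor improvement minus the
    independent one. The decomposition satisfies
    sum_j independent_j = GOF(full) - GOF(null).
    """
    k = len(predictors)
    if not 1 <= k <= 8:
        raise ValueError("hierarchical partitioning supports 1..8 predictors")
    g = _gof_values(frame, predictors, gof)
    rows = []
    for j in predictors:
        others = [p for p in predictors if p != j]
        indep = 0.0
        for h in range(k):
            level_sum = 0.0
            count = comb(k - 1, h)
            for subset in itertools.combinations(others, h):
                s = frozenset(subset)
                level_sum += g[s | {j}] - g[s]
            indep += level_sum / count
        indep /= k
        total = g[frozenset({j})]
        rows.append({"predictor": j, "independent": indep,
                     "joint": total - indep, "total": total})
    table = pd.DataFrame(rows).set_index("predictor")
    full = g[frozenset(predictors)]
    if abs(table["independent"].sum() - full) > 1e-8 * max(1.0, abs(full)):
        raise AssertionError("partitioning identity violated")
    return HierPartResult(table=table, gof_name=gof, gof_full=full)
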