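"""Retention odds of WGD duplicates per function group and linear modeling.

The degree of retention of a function group g after a WGD event w is the
odds ratio

    R_{g,w} = (D_{g,w} / S_{g,w}) / (D_{!g,w} / S_{!g,w})

where D and S count WGD-duplicate and WGD-singleton genes inside and
outside the group. R is related to group-level features with an ordinary
linear model pruned by backward elimination: refit, drop the feature with
the largest coefficient p-value, and keep the visited model whose overall
F-statistic is largest. Robustness is assessed by leave-one-group-out
refits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats.contingency import odds_ratio as _odds_ratio

__all__ = [
    "RetentionOdds",
    "LinearRetentionModel",
    "retention_odds",
    "filter_groups",
    "prefilter_features",
    "fit_retention_model",
    "leave_one_out_robustness",
]


@dataclass
class RetentionOdds:
    odds: float
    ci_low: float
    ci_high: float
    counts: tuple[int, int, int, int]  # D_g, S_g, D_not_g, S_not_g


def retention_odds(
    d_g: int, s_g: int, d_ng: int, s_ng: int, alpha: float = 0.05
) -> RetentionOdds:
    """Point estimate (D_g/S_g)/(D_!g/S_!g) with an exact conditional 95% CI.

    The CI inverts the noncentral hypergeometric distribution of the 2x2
    table conditional on its margins (central Fisher interval). A zero
    denominator yields an infinite point estimate with a one-sided CI and
    a warning.
    """
    for v in (d_g, s_g, d_ng, s_ng):
        if v < 0:
            raise ValueError("counts must be nonnegative")
    if s_g == 0 or d_ng == 0:
        warnings.warn("zero denominator count; odds ratio is infinite")
        point = float("inf")
    else:
        point = (d_g / s_g) / (d_ng / s_ng)
    table = [[d_g, s_g], [d_ng, s_ng]]
    res = _odds_ratio(table, kind="conditional")
    ci = res.confidence_interval(confidence_level=1 - alpha)
    return RetentionOdds(point, float(ci.low), float(ci.high),
                         (d_g, s_g, d_ng, s_ng))


def filter_groups(
    groups: pd.DataFrame,
    min_genes: int = 100,
    max_genes: int = 2000,
    min_pairs: int = 20,
) -> pd.DataFrame:
    """Keep groups with 100-2000 genes (inclusive) and >= 20 duplicate pairs.

    Needs columns ``gene_count`` and ``pair_count``; removals are logged
    via :mod:`logging`.
    """
    import logging

    keep = (
        groups["gene_count"].between(min_genes, max_genes)
        & (groups["pair_count"] >= min_pairs)
    )
    for name in groups.index[~keep]:
        logging.getLogger(__name__).info("filter_groups: removed %s", name)
    return groups[keep]


def prefilter_features(
    features: pd.DataFrame,
    odds: pd.Series,
    corr_threshold: float = 0.7,
    max_missing: float = 0.5,
    derived: set[str] | None = None,
    blacklist: set[str] | None = None,
) -> list[str]:
    """Reduce collinear candidate features before model fitting.

    Features on an explicit ``blacklist`` (e.g. anything derived from d_s)
    or with more than ``max_missing`` missing values or zero variance are
    removed first. Then, among each cluster of features with pairwise
    |r| > ``corr_threshold``, one representative is kept, preferring
    (1) the stronger marginal correlation with the odds, (2) features not
    flagged as ``derived`` from another feature, and (3) dropping the
    features correlated with more others.
    """
    derived = derived or set()
    blacklist = blacklist or set()
    cols = [c for c in features.columns if c not in blacklist]
    kept = []
    for c in cols:
        col = features[c]
        if col.isna().mean() > max_missing:
            warnings.warn(f"feature {c!r} removed: too many missing values")
            continue
        if col.std(skipna=True) == 0 or col.nunique(dropna=True) < 2:
            warnings.warn(f"feature {c!r} removed: constant")
            continue
        kept.append(c)
    if len(kept) < 2:
        return kept
    sub = features[kept]
    corr = sub.corr().abs()
    marginal = {
        c: abs(pd.concat([sub[c], odds], axis=1).corr().iloc[0, 1])
        for c in kept
    }
    n_conflicts = {
        c: int((corr.loc[c].drop(c) > corr_threshold).sum()) for c in kept
    }

    def priority(c):
        # higher tuple = kept in a conflict
        return (round(marginal[c], 12), c not in derived, -n_conflicts[c], c)

    order = sorted(kept, key=priority, reverse=True)
    selected: list[str] = []
    for c in order:
        if all(corr.loc[c, s] <= corr_threshold for s in selected):
            selected.append(c)
    return [c for c in kept if c in selected]


@dataclass
class LinearRetentionModel:
    features: list[str]
    coefficients: dict[str, float]  # includes "const"
    f_statistic: float
    r_squared: float
    p_value: float
    importance: dict[str, float]  # delta-R^2 on single-feature removal
    history: list[dict] = field(default_factory=list)


def _ols(y: np.ndarray, X: pd.DataFrame):
    design = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.OLS(y, design, missing="drop").fit()


def fit_retention_model(
    features: pd.DataFrame,
    odds: pd.Series,
    log_odds: bool = False,
) -> LinearRetentionModel:
    """Backward elimination maximizing the overall F-statistic.

    Starting from all candidate features, each step refits the OLS model
    and drops the feature with the largest coefficient p-value; every
    visited model's F-statistic is recorded and the globally best one is
    returned. With no informative features the intercept-only model (no
    features, F undefined) wins. ``log_odds`` regresses log(R) instead of
    R. Feature importance is the drop in R^2 when that feature alone is
    removed from the selected model.
    """
    y = np.log(odds.to_numpy(dtype=float)) if log_odds else odds.to_numpy(
        dtype=float)
    if len(features) < features.shape[1] + 2:
        raise ValueError("need at least n_features + 2 groups")
    current = list(features.columns)
    history = []
    best = None
    while current:
        fit = _ols(y, features[current])
        fstat = float(fit.fvalue) if np.isfinite(fit.fvalue) else -np.inf
        history.append({
            "features": list(current),
            "f_statistic": fstat,
            "r_squared": float(fit.rsquared),
            "p_value": float(fit.f_pvalue),
        })
        if best is None or fstat > best[0]:
            best = (fstat, list(current), fit)
        pvals = fit.pvalues.drop("const", errors="ignore")
        aliased = pvals.index[pvals.isna()]
        if len(aliased):
            warnings.warn(f"dropping aliased feature {aliased[0]!r}")
            current.remove(aliased[0])
            continue
        current.remove(pvals.idxmax())
    if y.std() == 0 or best is None or not np.isfinite(best[0]):
        return LinearRetentionModel(
            features=[], coefficients={"const": float(np.mean(y))},
            f_statistic=float("nan"), r_squared=0.0, p_value=float("nan"),
            importance={}, history=history,
        )
    _, sel, fit = best
    importance = {}
    for c in sel:
        reduced = [f for f in sel if f != c]
        if reduced:
            r2 = _ols(y, features[reduced]).rsquared
        else:
            r2 = 0.0
        importance[c] = float(fit.rsquared - r2)
    return LinearRetentionModel(
        features=sel,
        coefficients={k: float(v) for k, v in fit.params.items()},
        f_statistic=float(fit.fvalue),
        r_squared=float(fit.rsquared),
        p_value=float(fit.f_pvalue),
        importance=importance,
        history=history,
    )


def leave_one_out_robustness(
    features: pd.DataFrame,
    odds: pd.Series,
    log_odds: bool = False,
) -> pd.DataFrame:
    """Leave-one-group-out refits of the full elimination procedure.

    For every omitted group the whole backward-elimination search is
    re-run on the remaining groups. Returns one row per parameter (const +
    every feature selected in any refit) with mean, sd and relative sd of
    its estimate across refits (absent = not selected in that refit), plus
    the per-omission selected sets in ``DataFrame.attrs['selected']``.
    """
    if len(features) < 5:
        raise ValueError("need at least 5 groups")
    estimates: dict[str, dict] = {}
    selected: dict = {}
    for g in features.index:
        keep = features.index != g
        try:
            model = fit_retention_model(features[keep], odds[keep],
                                        log_odds=log_odds)
        except Exception as e:  # refit failure: record, exclude
            selected[g] = f"error: {e}"
            continue
        selected[g] = list(model.features)
        for k, v in model.coefficients.items():
            estimates.setdefault(k, {})[g] = v
    rows = []
    for k, vals in estimates.items():
        arr = np.array(list(vals.values()), dtype=float)
        mean, sd = float(arr.mean()), float(arr.std(ddof=1)) if len(
            arr) > 1 else 0.0
        rows.append({
            "parameter": k,
            "n_refits": len(arr),
            "mean": mean,
            "sd": sd,
            "relative_sd": sd / abs(mean) if mean != 0 else float("inf"),
        })
    out = pd.DataFrame(rows).set_index("parameter")
    out.attrs["selected"] = selected
    return out
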