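"""Duplicate-pair partitioning: extant copies vs their inferred ancestor.

Per pair and item (expression condition or binding site) the three states
of interest are O (both copies retain the ancestral state), I (exactly one
does — a "partitioned" item), and II (neither does). Observed grids and
fractions are compared against resampling nulls: random re-pairing of
pooled extant/ancestral values for the state grids, and random re-pairing
of genes (keeping each gene's own retention profile) for the pair-state
fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

from .ancestral import MISSING, AMBIGUOUS

__all__ = [
    "classify_pair_item",
    "classify_pairs",
    "ZScoreGrid",
    "permutation_zscores",
    "deviation_records",
    "pair_expression_summary",
    "novel_site_analysis",
]


def classify_pair_item(ancestral_state, state_a, state_b):
    """O/I/II call for one item; returns (cls, retained_by).

    ``retained_by`` is "A"/"B" for class I (the copy matching the
    ancestor), "both" for O and "neither" for II. Any missing or ambiguous
    input means the item should have been skipped upstream.
    """
    for s in (ancestral_state, state_a, state_b):
        if s == MISSING or s == AMBIGUOUS or s is None:
            raise ValueError("classify_pair_item requires resolved states")
    a = state_a == ancestral_state
    b = state_b == ancestral_state
    if a and b:
        return "O", "both"
    if a or b:
        return "I", "A" if a else "B"
    return "II", "neither"


def classify_pairs(
    pairs: pd.DataFrame,
    ancestral_calls: pd.DataFrame,
    extant_states: pd.DataFrame,
) -> pd.DataFrame:
    """Long per-pair x item classification table.

    ``pairs`` needs columns gene_a, gene_b, ancestor (node label of the
    pair's ancestor) and carries through ``event`` and ``ds`` when present.
    ``ancestral_calls`` is the consensus-call table (node, item, state);
    ambiguous calls and items with a missing extant value are dropped per
    item.
    """
    calls = ancestral_calls.set_index(["node", "item"])["state"].sort_index()
    if calls.index.has_duplicates:
        raise ValueError("ancestral_calls has duplicate (node, item) rows")
    carry = [c for c in ("event", "ds") if c in pairs.columns]
    rows = []
    for pr in pairs.itertuples(index=False):
        pair_id = f"{pr.gene_a}|{pr.gene_b}"
        for item in extant_states.columns:
            try:
                anc = calls.loc[(pr.ancestor, item)]
            except KeyError:
                continue
            if anc == AMBIGUOUS:
                continue
            sa = extant_states.at[pr.gene_a, item]
            sb = extant_states.at[pr.gene_b, item]
            if sa == MISSING or sb == MISSING:
                continue
            cls, ret = classify_pair_item(int(anc), int(sa), int(sb))
            row = {
                "pair": pair_id,
                "gene_a": pr.gene_a,
                "gene_b": pr.gene_b,
                "item": item,
                "ancestral_state": int(anc),
                "state_a": int(sa),
                "state_b": int(sb),
                "class": cls,
                "retained_by": ret,
            }
            for c in carry:
                row[c] = getattr(pr, c)
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ZScoreGrid:
    observed: np.ndarray
    perm_mean: np.ndarray
    perm_sd: np.ndarray
    z: np.ndarray  # NaN where the permutation sd is 0
    row_values: np.ndarray
    col_values: np.ndarray


def _grid_counts(rows, cols, row_vals, col_vals) -> np.ndarray:
    ri = np.searchsorted(row_vals, rows)
    ci = np.searchsorted(col_vals, cols)
    counts = np.zeros((len(row_vals), len(col_vals)), dtype=int)
    np.add.at(counts, (ri, ci), 1)
    return counts


def permutation_zscores(
    extant_states,
    ancestral_states,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> ZScoreGrid:
    """Observed (extant, ancestral) cell counts vs random re-pairings.

    The null re-pairs values drawn from the pooled extant and pooled
    ancestral sets (a permutation of the observed pairing), so each
    replicate preserves both marginal totals. z = (obs - mean) / sd; cells
    with zero permutation sd get z = NaN.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    ext = np.asarray(extant_states, dtype=int)
    anc = np.asarray(ancestral_states, dtype=int)
    if ext.size == 0 or ext.size != anc.size:
        raise ValueError("extant and ancestral pools must be non-empty and "
                         "equal length")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    row_vals = np.unique(ext)
    col_vals = np.unique(anc)
    observed = _grid_counts(ext, anc, row_vals, col_vals)
    perm = np.zeros((n_perm,) + observed.shape, dtype=int)
    for r in range(n_perm):
        perm[r] = _grid_counts(ext, rng.permutation(anc), row_vals, col_vals)
    mean = perm.mean(axis=0)
    sd = perm.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (observed - mean) / sd, np.nan)
    return ZScoreGrid(observed, mean, sd, z, row_vals, col_vals)


def deviation_records(classified: pd.DataFrame) -> pd.DataFrame:
    """Per pair x item deviations from the ancestral quartile.

    deviation = extant quartile - ancestral quartile, in -3..3; copy 1 is
    the copy with the higher-or-equal extant quartile, so dev1 >= dev2.
    """
    d_a = classified["state_a"] - classified["ancestral_state"]
    d_b = classified["state_b"] - classified["ancestral_state"]
    out = classified[["pair", "item"]].copy()
    out["dev1"] = np.maximum(d_a, d_b)
    out["dev2"] = np.minimum(d_a, d_b)
    return out


def pair_expression_summary(
    profiles: pd.DataFrame,
    pairs: pd.DataFrame,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    group_cols: tuple = (),
) -> pd.DataFrame:
    """Observed vs re-paired fractions of {both, partitioned, neither}.

    ``profiles`` is a gene x item boolean table: does the gene retain the
    ancestral state for that item. ``pairs`` has gene_a/gene_b (plus
    optional grouping columns such as event or subset; permutation is
    within group). The null re-pairs gene_b across pairs at random,
    keeping every gene's own retention profile intact. Returns one row per
    (group x class) with observed fraction, permutation mean/sd and z.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    if rng is None:
        rng = np.random.default_rng(seed)
    mat = profiles.astype(bool).to_numpy()
    pos = {g: i for i, g in enumerate(profiles.index)}

    def counts(a_rows, b_rows) -> np.ndarray:
        a = mat[a_rows]
        b = mat[b_rows]
        both = (a & b).sum()
        neither = (~a & ~b).sum()
        return np.array([both, a.size - both - neither, neither], dtype=float)

    group_cols = list(group_cols)
    grouped = pairs.groupby(group_cols, sort=True) if group_cols else [
        ((), pairs)
    ]
    rows = []
    obs_pooled = np.zeros(3)
    null_pooled = np.zeros((n_perm, 3))
    total_items = 0
    for key, grp in grouped:
        a_rows = np.array([pos[g] for g in grp["gene_a"]])
        b_rows = np.array([pos[g] for g in grp["gene_b"]])
        obs_c = counts(a_rows, b_rows)
        null_c = np.empty((n_perm, 3))
        for r in range(n_perm):
            null_c[r] = counts(a_rows, rng.permutation(b_rows))
        n_items = obs_c.sum()
        obs_pooled += obs_c
        null_pooled += null_c
        total_items += n_items
        obs = obs_c / n_items
        mean, sd = (null_c / n_items).mean(axis=0), (
            null_c / n_items).std(axis=0, ddof=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(sd > 0, (obs - mean) / sd, np.nan)
        for i, cls in enumerate(("both", "partitioned", "neither")):
            row = dict(zip(group_cols,
                           key if isinstance(key, tuple) else (key,)))
            row.update({
                "class": cls,
                "observed": obs[i],
                "expected_mean": mean[i],
                "expected_sd": sd[i],
                "z": z[i],
            })
            rows.append(row)
    if group_cols:
        # pooled statistic with within-group permutation null
        obs = obs_pooled / total_items
        nullf = null_pooled / total_items
        mean, sd = nullf.mean(axis=0), nullf.std(axis=0, ddof=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(sd > 0, (obs - mean) / sd, np.nan)
        for i, cls in enumerate(("both", "partitioned", "neither")):
            row = dict.fromkeys(group_cols, "pooled")
            row.update({
                "class": cls,
                "observed": obs[i],
                "expected_mean": mean[i],
                "expected_sd": sd[i],
                "z": z[i],
            })
            rows.append(row)
    return pd.DataFrame(rows)


def novel_site_analysis(
    designations: pd.DataFrame,
    ancestral_sites: pd.DataFrame,
    extant_sites: pd.DataFrame,
    alternative: str = "greater",
) -> dict:
    """Excess of novel binding sites in the non-ancestral copy.

    A novel site is present in an extant copy but absent in the inferred
    ancestor. ``designations`` has pair, gene_a, gene_b, ancestor,
    ancestral_copy ("A"/"B"); ``ancestral_sites`` is the consensus-call
    table restricted to sites (ambiguous calls are ignored per site);
    ``extant_sites`` a gene x site 0/1 table.

    Returns per-pair novel counts, the one-sided exact binomial sign test
    over pairs with >= 1 novel site (vs p0 = 0.5), and the pooled 2x2
    (copy type x site novelty) conditional odds ratio with Fisher's exact
    test.
    """
    calls = ancestral_sites.set_index(["node", "item"])["state"]
    per_pair = []
    table = np.zeros((2, 2), dtype=int)  # rows: non-anc, anc; cols: novel, inherited
    for pr in designations.itertuples(index=False):
        anc_gene = pr.gene_a if pr.ancestral_copy == "A" else pr.gene_b
        non_gene = pr.gene_b if pr.ancestral_copy == "A" else pr.gene_a
        novel = {anc_gene: 0, non_gene: 0}
        inherited = {anc_gene: 0, non_gene: 0}
        for site in extant_sites.columns:
            try:
                anc_state = calls.loc[(pr.ancestor, site)]
            except KeyError:
                continue
            if anc_state == AMBIGUOUS:
                continue
            for gene in (anc_gene, non_gene):
                present = extant_sites.at[gene, site]
                if present == MISSING:
                    continue
                if present and int(anc_state) == 0:
                    novel[gene] += 1
                elif present and int(anc_state) == 1:
                    inherited[gene] += 1
        table[0] += (novel[non_gene], inherited[non_gene])
        table[1] += (novel[anc_gene], inherited[anc_gene])
        per_pair.append({
            "pair": pr.pair,
            "novel_ancestral": novel[anc_gene],
            "novel_non_ancestral": novel[non_gene],
            "difference": novel[non_gene] - novel[anc_gene],
        })
    per_pair = pd.DataFrame(per_pair)
    with_novel = per_pair[
        (per_pair["novel_ancestral"] + per_pair["novel_non_ancestral"]) > 0
    ]
    n_trials = int(len(with_novel))
    n_success = int((with_novel["difference"] > 0).sum())
    if n_trials > 0:
        sign_p = float(
            stats.binomtest(n_success, n_trials, 0.5,
                            alternative=alternative).pvalue
        )
    else:
        sign_p = float("nan")
    if table.min() >= 0 and table.sum() > 0 and table.sum(axis=1).min() > 0:
        orr = _odds_ratio(table, kind="conditional")
        ci = orr.confidence_interval()
        fisher_p = float(stats.fisher_exact(table)[1])
        or_stat, or_lo, or_hi = float(orr.statistic), float(ci.low), float(ci.high)
        sample_or = (
            (table[0, 0] * table[1, 1]) / (table[0, 1] * table[1, 0])
            if table[0, 1] * table[1, 0] > 0 else float("inf")
        )
    else:  # pragma: no cover - degenerate
        or_stat = or_lo = or_hi = fisher_p = sample_or = float("nan")
    return {
        "per_pair": per_pair,
        "n_pairs_with_novel": n_trials,
        "n_nonancestral_more": n_success,
        "sign_test_p": sign_p,
        "table": table,
        "odds_ratio": or_stat,
        "sample_odds_ratio": float(sample_or),
        "odds_ratio_ci": (or_lo, or_hi),
        "fisher_p": fisher_p,
    }
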