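"""Synthetic data generators with recorded ground truth.

Everything downstream of the raw-data preprocessing that the package does
not do (normalized expression tables, binding-site tables, family trees,
WGD pair lists with d_s) can be generated here with known truth: Markov
states evolved along trees, duplicate-pair fates drawn from the analytic
three-state kinetics, and group feature tables whose retention odds are a
linear function of the features plus noise. All generators take a
:class:`numpy.random.Generator` (or seed) and are fully deterministic
given it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ancestral import MISSING, RateModel
from .dynamics import OdeSystem, ode_solution, PAIR_STATES
from .trees import Phylogeny, parse_newick

__all__ = [
    "random_tree",
    "simulate_states_on_tree",
    "simulate_pair_fates",
    "simulate_group_feature_table",
    "simulate_family_dataset",
]

#: default d_s windows per WGD event, ordered young to old
DS_WINDOWS = {"alpha": (0.3, 1.0), "beta": (1.0, 2.0), "gamma": (2.0, 3.5)}


def _rng(rng_or_seed) -> np.random.Generator:
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)


def random_tree(
    n_tips: int,
    rng=None,
    labels: list[str] | None = None,
    mean_edge: float = 0.3,
) -> Phylogeny:
    """Random rooted binary tree built by successive coalescent-style joins.

    Edge heights accumulate exponential increments with mean ``mean_edge``
    so branch lengths are i.i.d.-ish and strictly positive.
    """
    rng = _rng(rng)
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if labels is None:
        labels = [f"g{i}" for i in range(n_tips)]
    lineages = [(lab, 0.0) for lab in labels]  # (newick, height)
    height = 0.0
    while len(lineages) > 1:
        height += rng.exponential(mean_edge)
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        (na, ha) = lineages.pop(j)
        (nb, hb) = lineages.pop(i)
        merged = f"({na}:{height - ha:.10f},{nb}:{height - hb:.10f})"
        lineages.append((merged, height))
    return parse_newick(lineages[0][0] + ";")


def simulate_states_on_tree(
    tree: Phylogeny,
    Q: np.ndarray | RateModel,
    root_distribution=None,
    n_items: int = 1,
    rng=None,
    missing_rate: float = 0.0,
    item_names: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evolve ``n_items`` independent discrete characters along the tree.

    The root state is drawn from ``root_distribution`` (uniform by
    default); each edge applies the CTMC transition kernel expm(Q t) for
    its length. Returns (tip states, true internal-node states) as
    gene x item / node x item integer DataFrames. ``missing_rate``
    replaces that fraction of tip entries with MISSING.
    """
    rng = _rng(rng)
    if isinstance(Q, RateModel):
        Q = Q.Q
    Q = np.asarray(Q, dtype=float)
    k = Q.shape[0]
    if Q.shape != (k, k) or np.any(Q - np.diag(np.diag(Q)) < 0) or np.max(
            np.abs(Q.sum(axis=1))) > 1e-8:
        raise ValueError("Q must be a valid row-generator matrix")
    if root_distribution is None:
        root_distribution = np.full(k, 1.0 / k)
    root_distribution = np.asarray(root_distribution, dtype=float)
    arrays = tree.as_arrays()
    from scipy.linalg import expm

    P = {i: expm(Q * arrays.blen[i]) for i in range(arrays.n_nodes)
         if arrays.parent[i] >= 0}
    n = arrays.n_nodes
    states = np.empty((n, n_items), dtype=int)
    root = n - 1
    states[root] = rng.choice(k, size=n_items, p=root_distribution)
    for i in range(n - 2, -1, -1):
        parent_states = states[arrays.parent[i]]
        u = rng.random(n_items)
        cum = np.cumsum(P[i], axis=1)
        states[i] = (u[:, None] > cum[parent_states]).sum(axis=1)
    if item_names is None:
        item_names = [f"item{j}" for j in range(n_items)]
    is_leaf = arrays.is_leaf
    tips = pd.DataFrame(
        states[is_leaf],
        index=[arrays.labels[i] for i in range(n) if is_leaf[i]],
        columns=item_names,
    )
    if missing_rate > 0:
        mask = rng.random(tips.shape) < missing_rate
        tips = tips.mask(pd.DataFrame(mask, index=tips.index,
                                      columns=tips.columns), MISSING)
    anc = pd.DataFrame(
        states[~is_leaf],
        index=[arrays.labels[i] for i in range(n) if not is_leaf[i]],
        columns=item_names,
    )
    return tips.astype(int), anc


def simulate_pair_fates(
    n_pairs: int,
    rates: tuple[float, float, float, float],
    ds_sampler=None,
    initial_state=(1.0, 0.0, 0.0),
    rng=None,
    events: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Draw duplicate pairs with O/I/II fate from the pair kinetics.

    Each pair gets a d_s from ``ds_sampler(rng, size)`` (default: WGD-event
    windows from :data:`DS_WINDOWS`, events drawn with probabilities
    ``events``, default uniform) and a class drawn from the analytic state
    distribution at t = d_s. Columns: gene_a, gene_b, event, ds, true_class.
    """
    rng = _rng(rng)
    x, y, w, z = rates
    if min(rates) < 0:
        raise ValueError("rates must be nonnegative")
    if events is None:
        events = {e: 1 / 3 for e in DS_WINDOWS}
    names = list(events)
    ev = rng.choice(names, size=n_pairs, p=np.array(list(events.values())))
    if ds_sampler is None:
        lo = np.array([DS_WINDOWS[e][0] for e in ev])
        hi = np.array([DS_WINDOWS[e][1] for e in ev])
        ds = rng.uniform(lo, hi)
    else:
        ds = np.asarray(ds_sampler(rng, n_pairs), dtype=float)
        if ds.size != n_pairs or np.any(ds <= 0):
            raise ValueError("ds_sampler must return n_pairs positive values")
    system = OdeSystem("pair", x, y, w, z, p0=np.asarray(initial_state))
    probs = ode_solution(system, ds)
    u = rng.random(n_pairs)
    idx = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
    return pd.DataFrame({
        "gene_a": [f"p{i}a" for i in range(n_pairs)],
        "gene_b": [f"p{i}b" for i in range(n_pairs)],
        "event": ev,
        "ds": ds,
        "true_class": [PAIR_STATES[i] for i in idx],
    })


def simulate_group_feature_table(
    n_groups: int = 20,
    n_features: int = 11,
    true_coefficients: dict[str, float] | None = None,
    intercept: float = 2.0,
    noise_sd: float = 0.05,
    count_scale: int = 1000,
    background_odds: float = 0.5,
    rng=None,
) -> dict:
    """Group feature table whose retention odds follow a linear model.

    Features are Uniform(0, 1); the latent odds of group g is
    ``intercept + sum_j beta_j f_gj + N(0, noise_sd)`` (floored at 0.01).
    Duplicate/singleton counts per group are Binomial(count_scale, p_g)
    with p_g chosen so the group's duplicate odds are latent * background;
    the complement is a large background pool at ``background_odds`` so the
    empirical R_g converges to the latent odds as ``count_scale`` grows.

    Returns dict with ``features`` (DataFrame), ``counts`` (DataFrame
    D, S per group plus the background row), ``latent_odds`` (Series) and
    ``truth`` (the coefficient dict).
    """
    rng = _rng(rng)
    if true_coefficients is None:
        true_coefficients = {"f1": 1.5, "f2": -0.8}
    feat_names = [f"f{j + 1}" for j in range(n_features)]
    for name in true_coefficients:
        if name not in feat_names:
            raise ValueError(f"coefficient for unknown feature {name!r}")
    if n_groups < len(true_coefficients) + 2:
        raise ValueError("n_groups must exceed informative features + 2")
    X = pd.DataFrame(
        rng.uniform(0, 1, size=(n_groups, n_features)),
        index=[f"grp{i + 1}" for i in range(n_groups)],
        columns=feat_names,
    )
    if X.std().min() == 0:
        raise ValueError("degenerate design: constant feature")
    beta = np.array([true_coefficients.get(c, 0.0) for c in feat_names])
    latent = intercept + X.to_numpy() @ beta + rng.normal(
        0, noise_sd, size=n_groups)
    latent = np.maximum(latent, 0.01)
    group_odds = latent * background_odds
    p = group_odds / (1.0 + group_odds)
    D = rng.binomial(count_scale, p)
    S = count_scale - D
    # the complement of a group includes the other groups, whose odds sit
    # away from background_odds; a large background pool keeps that
    # contamination of the empirical complement odds below ~0.4%
    bg_n = 400 * count_scale * n_groups
    bg_p = background_odds / (1.0 + background_odds)
    bg_D = rng.binomial(bg_n, bg_p)
    counts = pd.DataFrame({"D": D, "S": S}, index=X.index)
    counts.loc["background"] = (bg_D, bg_n - bg_D)
    return {
        "features": X,
        "counts": counts,
        "latent_odds": pd.Series(latent, index=X.index, name="latent_odds"),
        "truth": dict(true_coefficients),
    }


def empirical_retention_odds(counts: pd.DataFrame) -> pd.Series:
    """R_g for each non-background group vs everything outside it."""
    tot_d, tot_s = counts["D"].sum(), counts["S"].sum()
    groups = [g for g in counts.index if g != "background"]
    vals = {}
    for g in groups:
        d_g, s_g = counts.at[g, "D"], counts.at[g, "S"]
        vals[g] = (d_g / s_g) / ((tot_d - d_g) / (tot_s - s_g))
    return pd.Series(vals, name="odds")


@dataclass
class FamilyDataset:
    """One synthetic gene-family cohort with full ground truth."""

    trees: dict[str, Phylogeny]
    expression: pd.DataFrame  # gene x condition continuous values
    tip_states: pd.DataFrame  # gene x condition quartile states
    true_ancestors: dict[str, pd.DataFrame]  # family -> node x item states
    sites: pd.DataFrame  # gene x site 0/1
    true_site_ancestors: dict[str, pd.DataFrame]
    pairs: pd.DataFrame  # gene_a, gene_b, family, ancestor, event, ds
    condition_meta: pd.DataFrame  # item, series, position


def simulate_family_dataset(
    n_families: int = 10,
    tips_per_family: int = 8,
    n_conditions: int = 20,
    n_sites: int = 12,
    expression_rate: float = 0.3,
    site_gain_loss: tuple[float, float] = (0.4, 0.6),
    missing_rate: float = 0.0,
    series_length: int = 4,
    mean_edge: float = 0.3,
    rng=None,
) -> FamilyDataset:
    """Cohort of families with duplicate (cherry) pairs and evolved states.

    Each family is a random tree whose first cherry (two-leaf clade)
    closest to the root is the WGD duplicate pair; quartile expression
    states evolve under a symmetric 4-state chain at ``expression_rate``
    and binding sites under an asymmetric binary gain/loss chain.
    Continuous expression values consistent with the simulated quartiles
    are emitted so the discretization stage can run end to end.
    Conditions are annotated into series of ``series_length`` for the
    time-series robustness checks.
    """
    rng = _rng(rng)
    cond_names = [f"c{j}" for j in range(n_conditions)]
    site_names = [f"s{j}" for j in range(n_sites)]
    Q_expr = RateModel(4, np.full(6, expression_rate), "symmetric").Q
    gain, loss = site_gain_loss
    Q_site = np.array([[-gain, gain], [loss, -loss]])
    trees, anc_e, anc_s = {}, {}, {}
    tips_e, tips_s, pair_rows = [], [], []
    events = list(DS_WINDOWS)
    for f in range(n_families):
        fam = f"fam{f}"
        labels = [f"{fam}_g{i}" for i in range(tips_per_family)]
        tree = random_tree(tips_per_family, rng, labels=labels,
                           mean_edge=mean_edge)
        for nd in tree.dendropy_tree.preorder_node_iter():
            if not nd.is_leaf():  # make internal labels unique across families
                nd.label = f"{fam}_{nd.label}"
        te, ae = simulate_states_on_tree(
            tree, Q_expr, n_items=n_conditions, rng=rng,
            missing_rate=missing_rate, item_names=cond_names)
        ts, as_ = simulate_states_on_tree(
            tree, Q_site, n_items=n_sites, rng=rng,
            missing_rate=missing_rate, item_names=site_names)
        trees[fam] = tree
        anc_e[fam], anc_s[fam] = ae, as_
        tips_e.append(te)
        tips_s.append(ts)
        # duplicate pair: a cherry (sister-leaf pair); its parent node is
        # the pre-duplication ancestor
        arrays = tree.as_arrays()
        cherry = None
        for i in range(arrays.n_nodes):
            kids = arrays.children[i]
            if len(kids) == 2 and all(not arrays.children[c] for c in kids):
                cherry = (arrays.labels[kids[0]], arrays.labels[kids[1]],
                          arrays.labels[i])
        ga, gb, anc = cherry
        event = events[f % len(events)]
        lo, hi = DS_WINDOWS[event]
        pair_rows.append({
            "gene_a": ga, "gene_b": gb, "family": fam, "ancestor": anc,
            "event": event, "ds": rng.uniform(lo, hi),
        })
    tip_states = pd.concat(tips_e)
    sites = pd.concat(tips_s)
    # continuous expression consistent with the quartile states: state q
    # maps into (q, q+1) with jitter; missing stays missing
    vals = tip_states.to_numpy().astype(float)
    noise = rng.uniform(0.05, 0.95, size=vals.shape)
    expr = np.where(vals >= 0, vals + noise, np.nan)
    expression = pd.DataFrame(expr, index=tip_states.index,
                              columns=tip_states.columns)
    n_series = max(1, n_conditions // series_length)
    meta = pd.DataFrame({
        "item": cond_names,
        "series": [f"ser{j // series_length % n_series}"
                   for j in range(n_conditions)],
        "position": [j % series_length for j in range(n_conditions)],
    })
    return FamilyDataset(
        trees=trees,
        expression=expression,
        tip_states=tip_states,
        true_ancestors=anc_e,
        sites=sites,
        true_site_ancestors=anc_s,
        pairs=pd.DataFrame(pair_rows),
        condition_meta=meta,
    )
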