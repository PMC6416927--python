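"""Asymmetry of ancestral-state partitioning between duplicate copies.

For a duplicate pair with n partitioned items (class I: exactly one copy
retains the ancestral state), k_A of which are retained by copy A, the
asymmetry score is

    Y = max(F_A, F_B) - (1 - max(F_A, F_B)) = |2 F_A - 1|,   F_A = k_A / n.

Y is 0 at a perfect 50/50 split and 1 when one copy inherits everything.
The copy with the larger share is designated the "ancestral" copy (ties
broken with the run RNG). The null keeps each pair's n fixed and draws
k_A ~ Binomial(n, 1/2) — every partitioned item lands in either copy
independently with equal probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AsymmetryRecord",
    "NullAsymmetry",
    "asymmetry_score",
    "asymmetry_records",
    "exact_mean_asymmetry",
    "grouped_bernoulli_null",
    "compare_to_null",
    "timeseries_robustness_subsets",
]

MIN_PARTITIONED = 5


@dataclass
class AsymmetryRecord:
    pair: object
    n: int
    k_a: int
    f_a: float
    y: float
    ancestral_copy: str  # "A" or "B"


@dataclass
class NullAsymmetry:
    replicate_means: np.ndarray
    per_pair_draws: np.ndarray  # (reps, n_pairs) null Y values
    exact_by_n: dict[int, float]

    @property
    def mean(self) -> float:
        return float(self.replicate_means.mean())


def asymmetry_score(
    k_a: int, n: int, pair=None, rng: np.random.Generator | None = None
) -> AsymmetryRecord:
    """Score one pair; ties (k_A = n/2) designate the ancestral copy at
    random using ``rng``."""
    if not 0 <= k_a <= n or n <= 0:
        raise ValueError(f"invalid counts k_a={k_a}, n={n}")
    f_a = k_a / n
    y = abs(2.0 * f_a - 1.0)
    if k_a * 2 == n:
        rng = np.random.default_rng() if rng is None else rng
        anc = "A" if rng.random() < 0.5 else "B"
    else:
        anc = "A" if f_a > 0.5 else "B"
    return AsymmetryRecord(pair=pair, n=n, k_a=k_a, f_a=f_a, y=y,
                           ancestral_copy=anc)


def asymmetry_records(
    partitioned: pd.DataFrame,
    min_partitioned: int = MIN_PARTITIONED,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-pair asymmetry from a table of partitioned items.

    ``partitioned`` needs columns ``pair`` and ``retained_by`` ("A"/"B").
    Pairs with fewer than ``min_partitioned`` partitioned items are
    excluded. Returns columns pair, n, k_a, f_a, y, ancestral_copy.
    """
    rng = np.random.default_rng() if rng is None else rng
    rows = []
    for pair, grp in partitioned.groupby("pair", sort=True):
        n = len(grp)
        if n < min_partitioned:
            continue
        k_a = int((grp["retained_by"] == "A").sum())
        rec = asymmetry_score(k_a, n, pair=pair, rng=rng)
        rows.append(vars(rec))
    return pd.DataFrame(
        rows, columns=["pair", "n", "k_a", "f_a", "y", "ancestral_copy"]
    )


def exact_mean_asymmetry(n: int) -> float:
    """E[Y | n] under k ~ Binomial(n, 1/2), by enumeration."""
    if n <= 0:
        raise ValueError("n must be positive")
    total = sum(comb(n, k) * abs(2 * k - n) for k in range(n + 1))
    return total / (2 ** n) / n


def grouped_bernoulli_null(
    n_list,
    reps: int = 1000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    min_partitioned: int = MIN_PARTITIONED,
) -> NullAsymmetry:
    """Null asymmetry distribution grouped by the observed per-pair n.

    Each replicate redraws every pair's k_A ~ Binomial(n, 1/2), scores Y
    per pair, and averages over pairs; ``reps`` replicate means are
    returned along with all per-pair draws and the exact E[Y | n] table.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n_arr = np.asarray(list(n_list), dtype=int)
    if n_arr.size == 0:
        raise ValueError("empty n_list")
    if np.any(n_arr < min_partitioned):
        raise ValueError(f"all n must be >= {min_partitioned}")
    k = rng.binomial(n_arr, 0.5, size=(reps, n_arr.size))
    y = np.abs(2.0 * k / n_arr - 1.0)
    exact = {int(n): exact_mean_asymmetry(int(n)) for n in np.unique(n_arr)}
    return NullAsymmetry(
        replicate_means=y.mean(axis=1),
        per_pair_draws=y,
        exact_by_n=exact,
    )


def compare_to_null(records: pd.DataFrame, null: NullAsymmetry) -> dict:
    """Observed-vs-null tests.

    Welch's two-sample t-test compares the observed per-pair Y values with
    the null per-pair draws (all replicates pooled); the two-sample
    Kolmogorov-Smirnov test compares the same two samples. With degenerate
    (zero-variance) input only the KS result is returned.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 asymmetry records")
    obs = records["y"].to_numpy(dtype=float)
    nul = null.per_pair_draws.ravel()
    ks = stats.ks_2samp(obs, nul)
    out = {
        "observed_mean": float(obs.mean()),
        "null_mean": float(nul.mean()),
        "null_replicate_mean": float(null.replicate_means.mean()),
        "ks_statistic": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "n_pairs": int(len(obs)),
    }
    if obs.std() > 0 or nul.std() > 0:
        t = stats.ttest_ind(obs, nul, equal_var=False)
        out["welch_t"] = float(t.statistic)
        out["welch_p"] = float(t.pvalue)
    return out


def timeseries_robustness_subsets(
    partitioned: pd.DataFrame,
    condition_meta: pd.DataFrame,
    min_partitioned: int = MIN_PARTITIONED,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Recompute mean asymmetry using only first / only last series elements.

    ``condition_meta`` needs columns ``item``, ``series`` and ``position``;
    within each series the smallest position is "first" and the largest
    "last". Conditions absent from the metadata are skipped with the subset
    marked incomplete. Returns one row per subset (full, first, last) with
    mean Y and the number of pairs surviving the min-partitioned filter.
    """
    rng = np.random.default_rng() if rng is None else rng
    meta = condition_meta.set_index("item")
    known = partitioned["item"].isin(meta.index)
    part = partitioned[known]
    first_items, last_items = set(), set()
    for _, grp in meta.groupby("series"):
        first_items.add(grp["position"].idxmin())
        last_items.add(grp["position"].idxmax())
    rows = []
    subsets = {
        "full": set(meta.index),
        "first": first_items,
        "last": last_items,
    }
    for name, items in subsets.items():
        sub = part[part["item"].isin(items)]
        recs = asymmetry_records(sub, min_partitioned=min_partitioned, rng=rng)
        rows.append({
            "subset": name,
            "n_pairs": int(len(recs)),
            "mean_y": float(recs["y"].mean()) if len(recs) else float("nan"),
        })
    return pd.DataFrame(rows)
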