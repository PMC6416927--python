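"""Ancestral state inference for gene-family trees.

Discrete character evolution (expression quartiles 0-3, binding-site
presence 0/1) is modeled as a continuous-time Markov chain on the rooted
family tree. Rates are estimated by maximum likelihood with the Felsenstein
pruning recursion, marginal ancestral posteriors come from an
inside-outside pass, and robustness is assessed by repeating the fit from
independent random initializations and forming a consensus call per node
and item: the modal state is reported only when it appears in more than
``consensus_min`` of ``consensus_runs`` runs and its marginal posterior
exceeds ``posterior_min``; everything else is AMBIGUOUS and is meant to be
excluded downstream.

Missing tip values are marginalized (partial likelihood 1 for every
state); the root state prior is uniform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .trees import Phylogeny, TreeArrays, midpoint_root  # noqa: F401  (re-export)

__all__ = [
    "MISSING",
    "AMBIGUOUS",
    "RateModel",
    "discretize_expression",
    "midpoint_root",
    "tree_log_likelihood",
    "marginal_ancestral_states",
    "fit_rate_model",
    "consensus_ancestral_calls",
]

MISSING = -1  # integer token in state arrays; "NA" in TSV
AMBIGUOUS = "ambiguous"


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

def discretize_expression(
    matrix: pd.DataFrame,
    experiments: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Map continuous expression to quartile states 0-3 per experiment.

    ``experiments`` maps an experiment name to the condition columns it
    covers; by default every column is its own experiment. Quartile
    boundaries are the empirical 25/50/75 percentiles of all non-missing
    values in the experiment. A value is assigned the number of boundaries
    strictly below it, so ties on a boundary collapse downward and a
    constant experiment maps to state 0 everywhere. Experiments with fewer
    than 4 non-missing values come back all-missing with a warning.
    """
    if experiments is None:
        experiments = {c: [c] for c in matrix.columns}
    out = pd.DataFrame(
        MISSING, index=matrix.index, columns=matrix.columns, dtype=int
    )
    for name, cols in experiments.items():
        block = matrix[cols].to_numpy(dtype=float)
        vals = block[np.isfinite(block)]
        if vals.size < 4:
            warnings.warn(
                f"experiment {name!r} has {vals.size} values (<4); "
                "all states set to missing"
            )
            continue
        bounds = np.percentile(vals, [25, 50, 75])
        states = np.searchsorted(bounds, block, side="left")
        states[~np.isfinite(block)] = MISSING
        out[cols] = states.astype(int)
    return out


# ---------------------------------------------------------------------------
# rate model
# ---------------------------------------------------------------------------

@dataclass
class RateModel:
    """CTMC generator over a discrete state alphabet.

    ``parameterization`` is one of:

    * ``"equal"`` — a single exchange rate for every transition;
    * ``"symmetric"`` — free rates with q_ij = q_ji (default);
    * ``"free"`` — all off-diagonal rates free.
    """

    n_states: int
    rates: np.ndarray  # free-rate vector, see param_count()
    parameterization: str = "symmetric"

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        expected = self.param_count(self.n_states, self.parameterization)
        if self.rates.shape != (expected,):
            raise ValueError(
                f"{self.parameterization} model with {self.n_states} states "
                f"needs {expected} rates, got {self.rates.shape}"
            )
        if np.any(self.rates < 0):
            raise ValueError("rates must be nonnegative")

    @staticmethod
    def param_count(k: int, parameterization: str) -> int:
        return {
            "equal": 1,
            "symmetric": k * (k - 1) // 2,
            "free": k * (k - 1),
        }[parameterization]

    @property
    def Q(self) -> np.ndarray:
        """Row-generator: Q[i, j] is the i->j rate, rows sum to zero."""
        k = self.n_states
        Q = np.zeros((k, k))
        if self.parameterization == "equal":
            Q[:] = self.rates[0]
        elif self.parameterization == "symmetric":
            iu = np.triu_indices(k, 1)
            Q[iu] = self.rates
            Q.T[iu] = self.rates
        else:  # free
            mask = ~np.eye(k, dtype=bool)
            Q[mask] = self.rates
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def transition_matrices(self, times: np.ndarray) -> np.ndarray:
        """P(t) = expm(Q t) for each t; shape (len(times), k, k)."""
        Q = self.Q
        times = np.asarray(times, dtype=float)
        if self.parameterization in ("equal", "symmetric"):
            # symmetric generator: eigendecomposition is real and cheap
            lam, U = np.linalg.eigh(Q)
            E = np.exp(np.multiply.outer(times, lam))  # (n, k)
            P = np.einsum("ik,nk,jk->nij", U, E, U)
        else:
            P = np.stack([expm(Q * t) for t in times])
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=2, keepdims=True)
        return P


# ---------------------------------------------------------------------------
# pruning likelihood and marginal reconstruction
# ---------------------------------------------------------------------------

def _tip_partials(
    arrays: TreeArrays, tips: pd.DataFrame, k: int
) -> np.ndarray:
    """Partial-likelihood array (n_nodes, n_items, k); missing tips -> 1."""
    n_items = tips.shape[1]
    L = np.ones((arrays.n_nodes, n_items, k))
    for label, node in arrays.leaf_index.items():
        try:
            states = tips.loc[label].to_numpy(dtype=int)
        except KeyError:
            raise KeyError(f"no tip states for leaf {label!r}")
        obs = states >= 0
        L[node, obs, :] = 0.0
        L[node, obs, states[obs]] = 1.0
    return L


def _pruning_pass(
    arrays: TreeArrays, tips: pd.DataFrame, model: RateModel
):
    """Return (partials L, per-edge messages M, transition mats P, root ll).

    ``M[i]`` is the message node i sends its parent:
    M[i](s_parent) = sum_j P_i[s_parent, j] L_i(j).
    """
    k = model.n_states
    L = _tip_partials(arrays, tips, k)
    P = model.transition_matrices(arrays.blen)
    M = np.ones_like(L)
    for i in range(arrays.n_nodes):
        for c in arrays.children[i]:
            L[i] *= M[c]
        if arrays.parent[i] >= 0:
            M[i] = L[i] @ P[i].T
    root = arrays.n_nodes - 1
    prior = np.full(k, 1.0 / k)
    site_lik = L[root] @ prior
    return L, M, P, np.log(np.clip(site_lik, 1e-300, None))


def tree_log_likelihood(
    tree: Phylogeny | TreeArrays, tips: pd.DataFrame, model: RateModel
) -> float:
    """Total log-likelihood of the tip states under ``model`` (uniform root
    prior), summed over items. Items whose tips are all missing contribute 0.
    """
    arrays = tree.as_arrays() if isinstance(tree, Phylogeny) else tree
    _, _, _, ll = _pruning_pass(arrays, tips, model)
    return float(ll.sum())


def marginal_ancestral_states(
    tree: Phylogeny | TreeArrays,
    tips: pd.DataFrame,
    model: RateModel,
    node: str | None = None,
):
    """Marginal posterior state distributions at internal nodes.

    Returns ``(posteriors, node_labels)`` where ``posteriors`` has shape
    (n_internal, n_items, k) and rows sum to 1, or the single node's
    (n_items, k) array when ``node`` is given.
    """
    arrays = tree.as_arrays() if isinstance(tree, Phylogeny) else tree
    k = model.n_states
    L, M, P, _ = _pruning_pass(arrays, tips, model)
    n_nodes = arrays.n_nodes
    root = n_nodes - 1
    U = np.ones_like(L)  # outside likelihoods
    U[root] = 1.0 / k
    for i in range(n_nodes - 1, -1, -1):
        kids = arrays.children[i]
        for c in kids:
            T = U[i].copy()
            for s in kids:
                if s != c:
                    T *= M[s]
            U[c] = T @ P[c]
    post = U * L
    norm = post.sum(axis=2, keepdims=True)
    post = np.divide(post, norm, out=np.full_like(post, 1.0 / k),
                     where=norm > 0)
    internal = [i for i in range(n_nodes) if arrays.children[i]]
    labels = [arrays.labels[i] for i in internal]
    if node is not None:
        if node not in labels:
            raise KeyError(f"internal node {node!r} not in tree")
        return post[internal[labels.index(node)]]
    return post[internal], labels


# ---------------------------------------------------------------------------
# rate fitting
# ---------------------------------------------------------------------------

def fit_rate_model(
    tree: Phylogeny | TreeArrays,
    tips: pd.DataFrame,
    n_restarts: int = 5,
    parameterization: str = "symmetric",
    n_states: int | None = None,
    rng: np.random.Generator | None = None,
    init_scale: tuple[float, float] = (0.01, 3.0),
) -> tuple[RateModel, float]:
    """Maximum-likelihood transition rates from random restarts.

    Rates are optimized on the log scale (positivity for free), each
    restart drawing its initial rates log-uniformly from ``init_scale``.
    Returns the best model and its log-likelihood.
    """
    arrays = tree.as_arrays() if isinstance(tree, Phylogeny) else tree
    rng = np.random.default_rng() if rng is None else rng
    if n_states is None:
        vals = tips.to_numpy()
        n_states = int(vals[vals >= 0].max()) + 1 if (vals >= 0).any() else 2
        n_states = max(n_states, 2)
    n_par = RateModel.param_count(n_states, parameterization)

    def neg_ll(log_rates):
        rates = np.exp(np.clip(log_rates, np.log(1e-8), np.log(1e4)))
        model = RateModel(n_states, rates, parameterization)
        return -tree_log_likelihood(arrays, tips, model)

    best = None
    lo, hi = np.log(init_scale[0]), np.log(init_scale[1])
    for _ in range(max(1, n_restarts)):
        x0 = rng.uniform(lo, hi, size=n_par)
        # Nelder-Mead on log-rates: derivative-free, does not overshoot
        # onto the flat high-rate plateau of the likelihood surface
        res = minimize(
            neg_ll, x0, method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 400 * n_par},
        )
        if best is None or res.fun < best.fun:
            best = res
    rates = np.exp(np.clip(best.x, np.log(1e-8), np.log(1e4)))
    model = RateModel(n_states, rates, parameterization)
    return model, -float(best.fun)


# ---------------------------------------------------------------------------
# consensus calls
# ---------------------------------------------------------------------------

def consensus_ancestral_calls(
    tree: Phylogeny,
    tips: pd.DataFrame,
    consensus_runs: int = 100,
    consensus_min: int = 50,
    posterior_min: float = 0.5,
    parameterization: str = "symmetric",
    n_states: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Repeated-restart consensus ancestral calls.

    Each run refits the rate model from one fresh random initialization and
    reconstructs marginal posteriors; a run votes for a state at a
    node x item when that state's posterior exceeds ``posterior_min``.
    The modal voted state is called when its support exceeds
    ``consensus_min`` (strictly); otherwise the call is AMBIGUOUS.

    Returns a long DataFrame: node, item, state (int or "ambiguous"),
    posterior (mean over supporting runs), support.
    """
    rng = np.random.default_rng() if rng is None else rng
    arrays = tree.as_arrays()
    if n_states is None:
        vals = tips.to_numpy()
        n_states = int(vals[vals >= 0].max()) + 1 if (vals >= 0).any() else 2
        n_states = max(n_states, 2)
    votes = None
    post_sum = None
    labels = None
    for _ in range(consensus_runs):
        model, _ = fit_rate_model(
            arrays, tips, n_restarts=1, parameterization=parameterization,
            n_states=n_states, rng=rng,
        )
        post, labels = marginal_ancestral_states(arrays, tips, model)
        if votes is None:
            votes = np.zeros(post.shape, dtype=int)
            post_sum = np.zeros(post.shape)
        win = post.argmax(axis=2)
        pmax = post.max(axis=2)
        ok = pmax > posterior_min
        idx0, idx1 = np.nonzero(ok)
        votes[idx0, idx1, win[ok]] += 1
        post_sum[idx0, idx1, win[ok]] += pmax[ok]
    modal = votes.argmax(axis=2)
    support = np.take_along_axis(votes, modal[..., None], axis=2)[..., 0]
    modal_post = np.take_along_axis(post_sum, modal[..., None], axis=2)[..., 0]
    mean_post = np.divide(
        modal_post, support, out=np.zeros_like(modal_post),
        where=support > 0,
    )
    called = (support > consensus_min) & (mean_post > posterior_min)
    records = []
    items = list(tips.columns)
    for ni, node in enumerate(labels):
        for ii, item in enumerate(items):
            records.append({
                "node": node,
                "item": item,
                "state": int(modal[ni, ii]) if called[ni, ii] else AMBIGUOUS,
                "posterior": float(mean_post[ni, ii]),
                "support": int(support[ni, ii]),
            })
    return pd.DataFrame.from_records(records)
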