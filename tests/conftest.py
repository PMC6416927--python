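import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

from dupdyn.simulate import random_tree


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_likelihood_and_posteriors(tree, tips, model):
    """Exhaustive sum over all internal-state assignments.

    Independent oracle for the pruning recursion: enumerates every joint
    assignment of states to internal nodes, accumulating the joint
    probability under a uniform root prior. Returns (total log-likelihood,
    {node_label: (n_items, k) posterior array}).
    """
    arr = tree.as_arrays()
    k = model.n_states
    P = {i: expm(model.Q * arr.blen[i])
         for i in range(arr.n_nodes) if arr.parent[i] >= 0}
    internal = [i for i in range(arr.n_nodes) if arr.children[i]]
    items = list(tips.columns)
    total_ll = 0.0
    post = {arr.labels[i]: np.zeros((len(items), k)) for i in internal}
    for j, item in enumerate(items):
        tip_state = {arr.leaf_index[g]: tips.at[g, item] for g in tips.index
                     if g in arr.leaf_index}
        total = 0.0
        acc = {i: np.zeros(k) for i in internal}
        for assign in itertools.product(range(k), repeat=len(internal)):
            amap = dict(zip(internal, assign))
            p_all = 1.0 / k
            for i in range(arr.n_nodes):
                if arr.parent[i] < 0:
                    continue
                if i in tip_state:
                    s = tip_state[i]
                    if s < 0:  # missing: marginalize
                        p_all *= P[i][amap[arr.parent[i]]].sum()
                        continue
                    amap[i] = s
                p_all *= P[i][amap[arr.parent[i]], amap[i]]
            total += p_all
            for i in internal:
                acc[i][amap[i]] += p_all
        total_ll += np.log(total)
        for i in internal:
            post[arr.labels[i]][j] = acc[i] / total
    return total_ll, post


@pytest.fixture
def small_random_trees():
    """A few random rooted trees with 2-6 tips for enumeration oracles."""
    gen = np.random.default_rng(777)
    trees = []
    for n_tips in (2, 3, 4, 5, 6):
        for _ in range(2):
            trees.append(random_tree(n_tips, gen))
    return trees
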