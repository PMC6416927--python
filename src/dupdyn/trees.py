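"""Phylogeny container, newick I/O, and midpoint rooting.

Family trees are consumed as newick with branch lengths (amino-acid scale,
used as given). Internally a tree is a thin wrapper around a
:class:`dendropy.Tree` plus a flattened array view used by the pruning
likelihood machinery.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "TreeArrays",
    "read_newick_tree",
    "parse_newick",
    "write_newick_tree",
    "midpoint_root",
]


class NewickError(ValueError):
    pass


@dataclass
class TreeArrays:
    """Flattened postorder view of a rooted tree.

    Nodes are indexed 0..n_nodes-1 in postorder (root last). ``parent[i]``
    is the postorder index of node i's parent (-1 for the root);
    ``blen[i]`` the length of the edge above node i (0 for the root).
    ``leaf_index`` maps a leaf label to its node index; ``children[i]``
    lists child indices.
    """

    parent: np.ndarray
    blen: np.ndarray
    children: list[list[int]]
    labels: list[str]
    leaf_index: dict[str, int]

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def is_leaf(self) -> np.ndarray:
        return np.array([len(c) == 0 for c in self.children])

    @property
    def internal_labels(self) -> list[str]:
        return [l for l, c in zip(self.labels, self.children) if c]


class Phylogeny:
    """A rooted (or rootable) gene-family tree with branch lengths."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._label_internal_nodes()
        self._validate()

    # -- construction helpers -------------------------------------------------

    def _label_internal_nodes(self) -> None:
        i = 0
        for nd in self._tree.preorder_node_iter():
            if nd.is_leaf():
                continue
            if nd.label is None or nd.label == "":
                while True:
                    cand = f"N{i}"
                    i += 1
                    if cand not in {n.label for n in self._tree if n.label}:
                        nd.label = cand
                        break

    def _validate(self) -> None:
        seen: set[str] = set()
        for leaf in self._tree.leaf_node_iter():
            lab = leaf.taxon.label if leaf.taxon else leaf.label
            if lab is None:
                raise NewickError("leaf without a label")
            if lab in seen:
                raise NewickError(f"duplicate leaf label: {lab!r}")
            seen.add(lab)
        root = self._tree.seed_node
        for nd in self._tree.preorder_node_iter():
            if nd is root:
                continue
            if nd.edge.length is None:
                raise NewickError(
                    f"missing branch length on edge above "
                    f"{self._node_name(nd)!r}"
                )
            if nd.edge.length < 0:
                raise NewickError(
                    f"negative branch length on edge above "
                    f"{self._node_name(nd)!r}"
                )

    @staticmethod
    def _node_name(nd: dendropy.Node) -> str:
        if nd.taxon is not None:
            return nd.taxon.label
        return nd.label or "<unnamed>"

    # -- basic queries --------------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaf_labels(self) -> list[str]:
        return [self._node_name(l) for l in self._tree.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    @property
    def is_rooted_binary_at_root(self) -> bool:
        return len(self._tree.seed_node.child_nodes()) == 2

    def copy(self) -> "Phylogeny":
        return Phylogeny(self._tree.clone(depth=1))

    def mrca_label(self, a: str, b: str) -> str:
        arr = self.as_arrays()
        try:
            ia, ib = arr.leaf_index[a], arr.leaf_index[b]
        except KeyError as e:
            raise KeyError(f"leaf not found: {e.args[0]!r}") from None
        ancestors = set()
        j = ia
        while j >= 0:
            ancestors.add(j)
            j = arr.parent[j]
        j = ib
        while j not in ancestors:
            j = arr.parent[j]
        return arr.labels[j]

    # -- array view -----------------------------------------------------------

    def as_arrays(self) -> TreeArrays:
        order = list(self._tree.postorder_node_iter())
        idx = {id(nd): i for i, nd in enumerate(order)}
        n = len(order)
        parent = np.full(n, -1, dtype=int)
        blen = np.zeros(n)
        children: list[list[int]] = [[] for _ in range(n)]
        labels: list[str] = []
        leaf_index: dict[str, int] = {}
        for i, nd in enumerate(order):
            labels.append(self._node_name(nd))
            if nd.parent_node is not None:
                parent[i] = idx[id(nd.parent_node)]
                blen[i] = nd.edge.length or 0.0
                children[parent[i]].append(i)
            if nd.is_leaf():
                leaf_index[labels[-1]] = i
        return TreeArrays(parent, blen, children, labels, leaf_index)

    # -- serialization --------------------------------------------------------

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            preserve_spaces=False,
            suppress_internal_node_labels=False,
        ).strip()
        return s

    def __repr__(self) -> str:  # pragma: no cover
        return f"Phylogeny(n_leaves={self.n_leaves})"


def parse_newick(text: str) -> Phylogeny:
    """Parse a newick string (branch lengths mandatory except at the root)."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderError as e:
        msg = str(e)
        if "Multiple occurrences" in msg or "duplicate" in msg.lower():
            raise NewickError(f"duplicate leaf label: {msg}") from e
        raise NewickError(msg) from e
    return Phylogeny(tree)


def read_newick_tree(path) -> Phylogeny:
    """Read one newick tree from ``path``.

    Raises :class:`NewickError` on a missing branch length (naming the edge)
    or a duplicate leaf label.
    """
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick_tree(tree: Phylogeny, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def midpoint_root(tree: Phylogeny) -> Phylogeny:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Total path lengths between leaves are preserved. When the midpoint
    falls exactly on the current root the tree comes back unchanged (up to
    internal-node relabeling); on any other node, the root is placed on
    the adjacent edge with a zero-length segment so the tree stays binary.
    A tree of total length zero is returned unchanged with a warning.
    """
    arrays = tree.as_arrays()
    if arrays.blen.sum() == 0.0:
        import warnings

        warnings.warn("tree has zero total length; midpoint rooting skipped")
        return tree.copy()

    # diameter endpoints and the midpoint's position along the path
    n = arrays.n_nodes
    root = n - 1
    depth = np.zeros(n)
    for i in range(n - 2, -1, -1):
        depth[i] = depth[arrays.parent[i]] + arrays.blen[i]
    chains = []  # node -> {ancestor: distance up}
    for i in range(n):
        chain, j = {}, i
        while j >= 0:
            chain[j] = depth[i] - depth[j]
            j = arrays.parent[j]
        chains.append(chain)
    leaves = list(arrays.leaf_index.values())
    best = (-1.0, None)
    for ai in leaves:
        for bi in leaves:
            if bi <= ai:
                continue
            mrca_d = min(chains[ai][j] + chains[bi][j]
                         for j in chains[ai] if j in chains[bi])
            if mrca_d > best[0]:
                best = (mrca_d, (ai, bi))
    diameter, (ai, bi) = best
    mrca = max(
        (j for j in chains[ai] if j in chains[bi]), key=lambda j: depth[j]
    )
    # walk from the deeper endpoint toward the mrca
    start = ai if chains[ai][mrca] >= diameter / 2 else bi
    target = diameter / 2
    node, cum = start, 0.0
    while cum + arrays.blen[node] < target - 1e-12:
        cum += arrays.blen[node]
        node = arrays.parent[node]
    offset = target - cum  # distance from `node` up along its edge

    t = tree.dendropy_tree.clone(depth=1)
    by_label = {}
    for nd in t.preorder_node_iter():
        by_label[Phylogeny._node_name(nd)] = nd
    child = by_label[arrays.labels[node]]
    edge_len = child.edge.length
    if abs(offset - edge_len) <= 1e-12 and arrays.parent[node] == root:
        return tree.copy()  # midpoint is the current root
    t.reroot_at_edge(
        child.edge,
        length1=edge_len - offset,  # tail (parent) side
        length2=offset,  # head (child) side
        update_bipartitions=False,
    )
    t.suppress_unifurcations()
    t.seed_node.edge.length = None
    for nd in t.preorder_node_iter():
        if nd is not t.seed_node and nd.edge.length is None:
            nd.edge.length = 0.0
        if not nd.is_leaf():
            nd.label = None
    return Phylogeny(t)
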