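"""Array-backed time-calibrated trees (chronograms).

A :class:`Chronogram` wraps a rooted, dated phylogeny whose branch lengths
are in millions of years (Myr) and whose node ages are measured in Ma before
present (present = 0 at the tips, root = maximum age).  Internally the tree
is stored as flat numpy arrays (parent pointers, child lists, branch lengths,
ages, a postorder index) so that likelihood and simulation code can run over
it without object traversal; dendropy is used for Newick I/O and pruning.
"""

from __future__ import annotations

import io
from typing import Sequence

import dendropy
import numpy as np

__all__ = ["Chronogram", "NotUltrametricError"]

#: default tolerance (Myr) for the ultrametricity check
ULTRAMETRIC_TOL = 1e-6


class NotUltrametricError(ValueError):
    """Raised when a tree violates ultrametricity beyond tolerance."""


class Chronogram:
    """A rooted, ultrametric, dated tree stored as flat arrays.

    Node indexing: tips occupy indices ``0 .. n_tips-1`` (in the order of
    ``tip_labels``); internal nodes follow; the root is the last index.
    ``parent[root] == -1`` and ``blen[root] == 0``.

    Parameters
    ----------
    parent
        Parent index per node (-1 for the root).
    blen
        Branch length (Myr) above each node; 0 for the root.
    tip_labels
        Tip names, one per tip index.
    """

    def __init__(self, parent: np.ndarray, blen: np.ndarray,
                 tip_labels: Sequence[str]):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.blen = np.asarray(blen, dtype=np.float64)
        self.tip_labels = list(tip_labels)
        self.n_nodes = len(self.parent)
        self.n_tips = len(self.tip_labels)
        if self.n_nodes != 0 and np.count_nonzero(self.parent == -1) != 1:
            raise ValueError("tree must have exactly one root")
        self.root = int(np.nonzero(self.parent == -1)[0][0])
        # children lists
        ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in range(self.n_nodes):
            p = self.parent[i]
            if p >= 0:
                ch[p].append(i)
        self.children = [np.asarray(c, dtype=np.int64) for c in ch]
        for i in range(self.n_tips):
            if len(self.children[i]):
                raise ValueError(f"node {i} indexed as tip but has children")
        self.postorder = self._postorder()
        self.age = self._compute_ages()

    # ------------------------------------------------------------------
    # construction
    # ------------------------------------------------------------------
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Chronogram":
        tree = tree.clone(depth=1)
        tree.suppress_unifurcations()
        leaves = [lf for lf in tree.leaf_node_iter()]
        labels = [lf.taxon.label if lf.taxon is not None else str(i)
                  for i, lf in enumerate(leaves)]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tip labels")
        index = {id(lf): i for i, lf in enumerate(leaves)}
        nxt = len(leaves)
        # assign internal indices in postorder so the root comes last
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                continue
            index[id(nd)] = nxt
            nxt += 1
        n = nxt
        parent = np.full(n, -1, dtype=np.int64)
        blen = np.zeros(n, dtype=np.float64)
        for nd in tree.postorder_node_iter():
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                blen[i] = float(nd.edge.length or 0.0)
        return cls(parent, blen, labels)

    @classmethod
    def from_newick(cls, source: str) -> "Chronogram":
        """Read from a Newick string or a path to a Newick file."""
        s = str(source)
        if "(" in s:
            tree = dendropy.Tree.get(data=s, schema="newick")
        else:
            tree = dendropy.Tree.get(path=s, schema="newick")
        return cls.from_dendropy(tree)

    # ------------------------------------------------------------------
    # export
    # ------------------------------------------------------------------
    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        nodes = [dendropy.Node() for _ in range(self.n_nodes)]
        for i in range(self.n_tips):
            nodes[i].taxon = taxa.new_taxon(self.tip_labels[i])
        for i in range(self.n_nodes):
            nodes[i].edge.length = float(self.blen[i])
            p = self.parent[i]
            if p >= 0:
                nodes[p].add_child(nodes[i])
        tree = dendropy.Tree(taxon_namespace=taxa)
        tree.seed_node = nodes[self.root]
        return tree

    def to_newick(self) -> str:
        out = io.StringIO()
        self.to_dendropy().write(file=out, schema="newick",
                                 suppress_rooting=True)
        return out.getvalue().strip()

    def write_newick(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # ------------------------------------------------------------------
    # structure
    # ------------------------------------------------------------------
    def _postorder(self) -> np.ndarray:
        order: list[int] = []
        stack = [self.root] if self.n_nodes else []
        while stack:
            nd = stack.pop()
            order.append(nd)
            stack.extend(self.children[nd])
        return np.asarray(order[::-1], dtype=np.int64)

    def _compute_ages(self) -> np.ndarray:
        # depth from root, then age = max depth - depth
        depth = np.zeros(self.n_nodes)
        for nd in self.postorder[::-1]:
            p = self.parent[nd]
            if p >= 0:
                depth[nd] = depth[p] + self.blen[nd]
        if self.n_nodes == 0:
            return depth
        return depth.max() - depth

    @property
    def root_age(self) -> float:
        return float(self.age[self.root])

    @property
    def is_binary(self) -> bool:
        return all(len(self.children[i]) == 2
                   for i in range(self.n_tips, self.n_nodes))

    @property
    def total_length(self) -> float:
        return float(self.blen.sum())

    def is_ultrametric(self, tol: float = ULTRAMETRIC_TOL) -> bool:
        tip_ages = self.age[: self.n_tips]
        return bool(np.all(np.abs(tip_ages) <= tol)) if self.n_tips else True

    def assert_ultrametric(self, tol: float = ULTRAMETRIC_TOL) -> None:
        if not self.is_ultrametric(tol):
            worst = float(np.abs(self.age[: self.n_tips]).max())
            raise NotUltrametricError(
                f"tree is not ultrametric: max tip age deviation {worst:g} Myr "
                f"exceeds tolerance {tol:g}")

    def binary_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(postorder, left-child, right-child) arrays for a binary tree.

        ``left[i] == right[i] == -1`` for tips.
        """
        if not self.is_binary:
            raise ValueError("operation requires a strictly bifurcating tree")
        left = np.full(self.n_nodes, -1, dtype=np.int64)
        right = np.full(self.n_nodes, -1, dtype=np.int64)
        for i in range(self.n_tips, self.n_nodes):
            left[i], right[i] = self.children[i]
        return self.postorder, left, right

    def tip_index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.tip_labels)}

    def clade_tips(self, node: int) -> np.ndarray:
        """Tip indices descending from ``node`` (node itself if a tip)."""
        out: list[int] = []
        stack = [node]
        while stack:
            nd = stack.pop()
            if nd < self.n_tips:
                out.append(nd)
            else:
                stack.extend(self.children[nd])
        return np.asarray(sorted(out), dtype=np.int64)

    def prune_to(self, keep_labels: Sequence[str]) -> "Chronogram":
        """Subtree induced by ``keep_labels`` (unifurcations suppressed).

        The result is the crown subtree of the retained tips: its root is
        their most recent common ancestor and carries no stem edge.
        """
        keep = set(keep_labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise KeyError(f"labels not in tree: {sorted(missing)[:5]}")
        if len(keep) < 2:
            raise ValueError("cannot prune below 2 tips")
        tree = self.to_dendropy()
        taxa = [t for t in tree.taxon_namespace if t.label in keep]
        tree.retain_taxa(taxa)
        tree.seed_node.edge.length = 0.0
        return Chronogram.from_dendropy(tree)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<Chronogram {self.n_tips} tips, root age "
                f"{self.root_age:.3f} Ma>")
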