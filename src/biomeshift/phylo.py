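"""Rooted, dated phylogenies.

Trees are read and written through :mod:`dendropy` but held internally as
flat arrays (parent pointers, branch lengths, node ages) convenient for
pruning-algorithm likelihoods and stochastic mapping.  Branch lengths are in
millions of years (Ma); node ages are measured back from the present, taken
to be the age of the deepest tip (so an ultrametric tree has all tips at age
zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["Phylogeny", "PhylogenyError", "read_newick", "write_newick"]


class PhylogenyError(ValueError):
    """Raised when a tree violates the structural requirements."""


@dataclass
class Phylogeny:
    """A rooted binary tree with branch lengths in Ma.

    Nodes are indexed ``0 .. n_nodes-1`` with tips first (``0 .. n_tips-1``,
    in the order of ``tip_labels``) and internal nodes in postorder, the root
    last.  ``parent[root] == -1``; ``branch_lengths[root]`` is the root edge
    length (0 if absent) and is ignored by all computations.
    """

    tip_labels: list[str]
    parent: np.ndarray          # (n_nodes,) int
    branch_lengths: np.ndarray  # (n_nodes,) float, edge above each node
    children: dict[int, tuple[int, int]]  # internal node -> (left, right)

    ages: np.ndarray = field(init=False)      # (n_nodes,) Ma before present
    postorder: np.ndarray = field(init=False)  # internal nodes, children-first

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.branch_lengths = np.asarray(self.branch_lengths, dtype=float)
        n = self.n_nodes
        if len(self.tip_labels) != len(set(self.tip_labels)):
            dupes = sorted({t for t in self.tip_labels if self.tip_labels.count(t) > 1})
            raise PhylogenyError(f"duplicate tip labels: {dupes}")
        if self.n_tips < 2:
            raise PhylogenyError("a tree needs at least 2 tips")
        if np.any(self.branch_lengths < 0):
            bad = int(np.where(self.branch_lengths < 0)[0][0])
            raise PhylogenyError(f"negative branch length on node {bad}")
        # depths from root, then ages from the deepest tip
        depth = np.zeros(n)
        order = self.preorder()
        for v in order:
            p = self.parent[v]
            if p >= 0:
                depth[v] = depth[p] + self.branch_lengths[v]
        height = depth[: self.n_tips].max()
        self.ages = height - depth
        # numerical zero for ultrametric tips
        self.ages[np.abs(self.ages) < 1e-9] = 0.0
        self.postorder = np.array(
            [v for v in order[::-1] if v in self.children], dtype=int
        )
        if not self.is_ultrametric():
            warnings.warn(
                "tree is not ultrametric; branch strata are determined by "
                "absolute node ages",
                stacklevel=3,
            )

    # -- basic properties -------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.where(self.parent < 0)[0][0])

    @property
    def height(self) -> float:
        return float(self.ages[self.root])

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        return bool(np.all(np.abs(self.ages[: self.n_tips]) <= tol * max(1.0, self.height)))

    def preorder(self) -> list[int]:
        root = int(np.where(self.parent < 0)[0][0])
        order, stack = [], [root]
        while stack:
            v = stack.pop()
            order.append(v)
            if v in self.children:
                stack.extend(self.children[v])
        return order

    def tip_index(self, label: str) -> int:
        return self.tip_labels.index(label)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        leaves = [lf for lf in tree.leaf_node_iter()]
        labels = []
        for lf in leaves:
            if lf.taxon is None or not lf.taxon.label:
                raise PhylogenyError("unlabelled tip in tree")
            labels.append(lf.taxon.label)
        internals = [nd for nd in tree.postorder_node_iter() if not nd.is_leaf()]
        for nd in internals:
            k = len(nd.child_nodes())
            if k != 2:
                name = nd.taxon.label if nd.taxon else (
                    "node above {" + ",".join(
                        sorted(l.taxon.label for l in nd.leaf_iter() if l.taxon)[:4]
                    ) + (",...}" if sum(1 for _ in nd.leaf_iter()) > 4 else "}")
                )
                raise PhylogenyError(
                    f"polytomy (or unifurcation) of degree {k} at {name}; "
                    "trees must be strictly binary"
                )
        index = {}
        for i, lf in enumerate(leaves):
            index[lf] = i
        for j, nd in enumerate(internals):
            index[nd] = len(leaves) + j
        n = len(leaves) + len(internals)
        parent = np.full(n, -1, dtype=int)
        blen = np.zeros(n)
        children: dict[int, tuple[int, int]] = {}
        for nd, i in index.items():
            if nd.parent_node is not None:
                parent[i] = index[nd.parent_node]
            if nd.edge.length is not None:
                blen[i] = float(nd.edge.length)
            elif nd.parent_node is not None:
                lab = nd.taxon.label if nd.taxon else f"internal node {i}"
                raise PhylogenyError(f"missing branch length above {lab}")
            if not nd.is_leaf():
                l, r = nd.child_nodes()
                children[i] = (index[l], index[r])
        return cls(labels, parent, blen, children)

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:
            raise PhylogenyError(f"could not parse Newick: {exc}") from exc
        return cls.from_dendropy(tree)

    def to_newick(self) -> str:
        def render(v: int) -> str:
            if v < self.n_tips:
                core = self.tip_labels[v]
            else:
                l, r = self.children[v]
                core = f"({render(l)},{render(r)})"
            if self.parent[v] >= 0:
                core += f":{self.branch_lengths[v]:.12g}"
            return core

        return render(self.root) + ";"


def read_newick(path) -> Phylogeny:
    """Read a rooted binary Newick tree with branch lengths from ``path``."""
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise PhylogenyError(f"{path}: empty tree file")
    return Phylogeny.from_newick(text)


def write_newick(tree: Phylogeny, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
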