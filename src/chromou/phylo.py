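"""Rooted ultrametric phylogenies and the time matrices trait models consume.

Trees are read from Newick (via :mod:`dendropy`) into a flat, immutable
array representation: nodes are integers, tips occupy indices
``0 .. n_tips-1`` in left-to-right Newick order, and every matrix produced
downstream (shared time, patristic distance, OU/BM covariances, regime
weights) indexes rows by that fixed tip order.

The two matrices that drive every covariance computation are

* ``shared_time[i, j]`` — time from the root to the most recent common
  ancestor of tips *i* and *j* (the Brownian-motion covariance up to a
  rate constant), and
* ``distance[i, j]`` — patristic distance ``t_i + t_j - 2 * shared_time``.

Analyses assume a unit-height ultrametric tree; :func:`scale_to_unit_height`
performs the rescaling and :meth:`Phylogeny.assert_ultrametric` enforces the
tolerance (relative 1e-6 of tree height).  Trees that fail it are rejected,
never silently stretched.  Polytomies pass through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import dendropy

__all__ = [
    "Phylogeny",
    "TimeMatrices",
    "NewickError",
    "UltrametricityError",
    "parse_newick",
    "scale_to_unit_height",
    "time_matrices",
    "prune_to_tips",
]

#: relative tolerance on tip depths for a tree to count as ultrametric
ULTRAMETRIC_RTOL = 1e-6


class NewickError(ValueError):
    """Raised when a Newick string cannot be parsed into a valid tree."""


class UltrametricityError(ValueError):
    """Raised when an operation requires an ultrametric tree and gets none."""


@dataclass(frozen=True)
class Phylogeny:
    """A rooted tree with branch lengths, in flat array form.

    Attributes
    ----------
    tip_labels:
        Unique tip names, in left-to-right Newick order.  Tip *i* is node
        *i*; internal nodes follow in postorder.
    parent:
        ``parent[v]`` is the parent node of ``v``; ``-1`` at the root.
    branch_length:
        Length of the branch above each node; ``0.0`` at the root (any
        root-edge length in the input is discarded).
    root:
        Index of the root node.
    """

    tip_labels: tuple
    parent: np.ndarray
    branch_length: np.ndarray
    root: int

    def __post_init__(self):
        object.__setattr__(self, "parent", np.asarray(self.parent, dtype=np.intp))
        object.__setattr__(
            self, "branch_length", np.asarray(self.branch_length, dtype=float)
        )
        if (self.parent == -1).sum() != 1 or self.parent[self.root] != -1:
            raise ValueError("tree must have exactly one root")
        if np.any(self.branch_length < 0):
            raise ValueError("negative branch length")
        if len(set(self.tip_labels)) != len(self.tip_labels):
            dup = sorted({t for t in self.tip_labels if list(self.tip_labels).count(t) > 1})
            raise NewickError(f"duplicate tip label(s): {', '.join(dup)}")

    # -- basic structure -------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def children(self) -> list:
        """Child lists per node (empty for tips)."""
        ch: list = [[] for _ in range(self.n_nodes)]
        for v, p in enumerate(self.parent):
            if p >= 0:
                ch[p].append(v)
        return ch

    def preorder(self) -> list:
        """Node indices, parents before children."""
        ch = self.children()
        order, stack = [], [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(ch[v]))
        return order

    def depths(self) -> np.ndarray:
        """Time from the root to each node."""
        d = np.zeros(self.n_nodes)
        for v in self.preorder():
            p = self.parent[v]
            if p >= 0:
                d[v] = d[p] + self.branch_length[v]
        return d

    @property
    def height(self) -> float:
        """Maximum root-to-tip depth."""
        return float(self.depths()[: self.n_tips].max())

    # -- validation ------------------------------------------------------
    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        td = self.depths()[: self.n_tips]
        h = td.max()
        return bool(h > 0 and (h - td.min()) <= rtol * h) or self.n_tips == 1

    def assert_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> None:
        if not self.is_ultrametric(rtol):
            td = self.depths()[: self.n_tips]
            raise UltrametricityError(
                f"tree is not ultrametric: tip depths span "
                f"[{td.min():.6g}, {td.max():.6g}] (rtol={rtol:g})"
            )

    # -- serialization ---------------------------------------------------
    def to_newick(self) -> str:
        ch = self.children()

        def sub(v: int) -> str:
            if not ch[v]:
                core = self.tip_labels[v]
            else:
                core = "(" + ",".join(sub(c) for c in ch[v]) + ")"
            if v == self.root:
                return core
            return f"{core}:{self.branch_length[v]:.12g}"

        return sub(self.root) + ";"

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        nodes = list(tree.preorder_node_iter())
        leaves = [n for n in tree.leaf_node_iter()]
        internals = [n for n in tree.postorder_internal_node_iter()]
        index: dict = {}
        labels = []
        for i, leaf in enumerate(leaves):
            index[id(leaf)] = i
            lbl = leaf.taxon.label if leaf.taxon is not None else leaf.label
            if lbl is None:
                raise NewickError("unlabeled tip")
            labels.append(str(lbl))
        for j, nd in enumerate(internals, start=len(leaves)):
            index[id(nd)] = j
        n_nodes = len(leaves) + len(internals)
        parent = np.full(n_nodes, -1, dtype=np.intp)
        blen = np.zeros(n_nodes)
        root = index[id(tree.seed_node)] if internals else None
        for nd in nodes:
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    who = labels[i] if i < len(leaves) else "an internal node"
                    raise NewickError(f"missing branch length on the edge above {who}")
                blen[i] = float(nd.edge.length)
        if root is None:
            # bare single-label input with no parenthesized structure
            raise NewickError("tree has no branching structure and no branch length")
        return cls(tuple(labels), parent, blen, root)


@dataclass(frozen=True)
class TimeMatrices:
    """Shared-time and patristic-distance matrices in fixed tip order.

    Invariants: ``shared_time[i, i] == tip_depth[i]`` and
    ``distance == tip_depth[:, None] + tip_depth[None, :] - 2 * shared_time``.
    """

    shared_time: np.ndarray
    distance: np.ndarray
    tip_depth: np.ndarray


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    Branch lengths are required on every edge (a root edge, if present, is
    ignored).  Tip order is the left-to-right order of the string.  The
    parser does *not* enforce ultrametricity; that check happens where a
    clock is actually required.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"malformed newick: {exc}") from exc
    if not any(True for _ in tree.leaf_node_iter()):
        raise NewickError("tree has no tips")
    return Phylogeny.from_dendropy(tree)


def scale_to_unit_height(tree: Phylogeny, rtol: float = ULTRAMETRIC_RTOL) -> Phylogeny:
    """Divide all branch lengths by the tree height so that T = 1.

    Idempotent; requires an ultrametric tree of positive height.
    """
    tree.assert_ultrametric(rtol)
    T = tree.height
    if T <= 0:
        raise ValueError("zero-height tree cannot be scaled")
    return Phylogeny(
        tree.tip_labels, tree.parent, tree.branch_length / T, tree.root
    )


def time_matrices(tree: Phylogeny) -> TimeMatrices:
    """Shared time to the MRCA and patristic distance for every tip pair.

    Each pair is assigned its shared time exactly once, at the pair's MRCA,
    by sweeping internal nodes in postorder and crossing the tip sets of
    their child subtrees.
    """
    n = tree.n_tips
    depth = tree.depths()
    s = np.zeros((n, n))
    np.fill_diagonal(s, depth[:n])
    ch = tree.children()
    tips_below: list = [None] * tree.n_nodes
    # postorder: tips are 0..n-1; internals were appended in postorder
    for v in range(n):
        tips_below[v] = [v]
    for v in range(n, tree.n_nodes):
        groups = [tips_below[c] for c in ch[v]]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                for i in groups[a]:
                    for j in groups[b]:
                        s[i, j] = s[j, i] = depth[v]
        tips_below[v] = [t for g in groups for t in g]
    t = depth[:n]
    d = t[:, None] + t[None, :] - 2.0 * s
    np.fill_diagonal(d, 0.0)
    return TimeMatrices(shared_time=s, distance=d, tip_depth=t)


def prune_to_tips(tree: Phylogeny, labels: Iterable[str]) -> Phylogeny:
    """Restrict the tree to a subset of tips (e.g. one clade).

    Uses dendropy's taxon extraction; unifurcations created by pruning are
    suppressed, and the returned tree is rooted at the MRCA of the kept
    tips.  The result is *not* rescaled — compose with
    :func:`scale_to_unit_height` when a unit-height clade subtree is needed.
    """
    keep = list(dict.fromkeys(labels))
    missing = sorted(set(keep) - set(tree.tip_labels))
    if missing:
        raise KeyError(f"tips not in tree: {', '.join(missing)}")
    if len(keep) < 2:
        raise ValueError("need at least 2 tips to prune to")
    dtree = dendropy.Tree.get(
        data=tree.to_newick(), schema="newick", preserve_underscores=True
    )
    sub = dtree.extract_tree_with_taxa_labels(labels=keep)
    sub.seed_node.edge.length = None
    out = Phylogeny.from_dendropy(sub)
    # extraction may leave a root with a single child; collapse it
    ch = out.children()
    while len(ch[out.root]) == 1:
        only = ch[out.root][0]
        parent = out.parent.copy()
        parent[only] = -1
        blen = out.branch_length.copy()
        blen[only] = 0.0
        keep_idx = [v for v in range(out.n_nodes) if v != out.root]
        remap = {v: i for i, v in enumerate(keep_idx)}
        parent2 = np.array(
            [remap[parent[v]] if parent[v] >= 0 else -1 for v in keep_idx],
            dtype=np.intp,
        )
        out = Phylogeny(
            out.tip_labels, parent2, blen[keep_idx], remap[only]
        )
        ch = out.children()
    return out
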