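"""Parsimony regime painting and the selection-weighted design matrix.

A *regime* is a categorical niche (habitat light class, growth form, ...)
assigned to every branch of the tree.  Tip states are observed; internal
states are reconstructed by minimum-change (Fitch) parsimony and each
branch inherits the state of the node below it, i.e. a shift sits at the
top of the branch on which the state changes.

Under an Ornstein-Uhlenbeck model with selection strength ``alpha``, the
expected tip value is a convex combination of the regime optima: a lineage
segment in regime *k* spanning root-times ``(t_a, t_b]`` on a unit-height
tree contributes ``exp(-alpha * (1 - t_b)) - exp(-alpha * (1 - t_a))`` to
the weight of *k*, and the root's residual influence ``exp(-alpha)`` is
folded into the root regime's column.  Rows of the resulting weight matrix
telescope to exactly 1 for every ``alpha > 0``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .phylo import Phylogeny

__all__ = ["RegimePainting", "RegimeWeightMatrix", "fitch_reconstruct", "regime_weights"]


@dataclass(frozen=True)
class RegimePainting:
    """One regime per branch (indexed by the child node) plus the root state.

    ``node_state[v]`` is the regime index of node ``v``; for a non-root node
    this is the regime painted on the branch above it.  ``change_count`` is
    the number of state changes along branches — the parsimony minimum when
    the painting comes from :func:`fitch_reconstruct`, the realized number
    of shift events for simulated paintings.
    """

    states: tuple
    node_state: np.ndarray
    root_regime: int
    change_count: int

    @property
    def n_states(self) -> int:
        return len(self.states)

    def branch_regime(self, node: int) -> int:
        return int(self.node_state[node])

    def tip_states(self, tree: Phylogeny) -> dict:
        return {
            lbl: self.states[self.node_state[i]]
            for i, lbl in enumerate(tree.tip_labels)
        }

    def to_table(self, tree: Phylogeny):
        """Two-column (node, regime) export for audit or plotting."""
        import pandas as pd

        names = [
            tree.tip_labels[v] if v < tree.n_tips else f"node{v}"
            for v in range(tree.n_nodes)
        ]
        return pd.DataFrame(
            {"node": names, "regime": [self.states[s] for s in self.node_state]}
        )


@dataclass(frozen=True)
class RegimeWeightMatrix:
    """Tips x regimes matrix of optimum weights at a given alpha."""

    W: np.ndarray
    alpha: float
    states: tuple


def fitch_reconstruct(
    tree: Phylogeny,
    tip_states: Mapping[str, str],
    tie_rule: str = "alphabetical",
) -> RegimePainting:
    """Minimum-change ancestral regimes with a deterministic tie rule.

    The bottom-up pass is unit-cost Sankoff dynamic programming (identical
    to Fitch set operations on binary trees, and exact on polytomies);
    ``change_count`` is therefore the true parsimony minimum.  The top-down
    pass keeps the parent's state whenever it attains the child's minimum
    score, otherwise falls back to ``tie_rule`` ("alphabetical": smallest
    index in the sorted label order).  At the root, ties between
    minimum-cost states go to the state held by the most tips (placing
    changes as tipward as possible), then alphabetical.
    """
    if tie_rule != "alphabetical":
        raise ValueError(f"unknown tie rule: {tie_rule!r}")
    missing = [t for t in tree.tip_labels if t not in tip_states]
    if missing:
        raise KeyError(f"tips without a state: {', '.join(missing[:5])}")
    states = tuple(sorted({str(tip_states[t]) for t in tree.tip_labels}))
    idx = {s: k for k, s in enumerate(states)}
    K = len(states)
    n_nodes = tree.n_nodes
    INF = np.inf
    cost = np.full((n_nodes, K), 0.0)
    ch = tree.children()
    order = tree.preorder()
    for v in reversed(order):  # postorder
        if not ch[v]:
            st = str(tip_states[tree.tip_labels[v]])
            cost[v, :] = INF
            cost[v, idx[st]] = 0.0
        else:
            acc = np.zeros(K)
            for c in ch[v]:
                # min over child state s' of cost[c, s'] + [s' != s]
                m = cost[c].min()
                acc += np.minimum(cost[c], m + 1.0)
            cost[v, :] = acc
    change_count = int(round(cost[tree.root].min()))
    # root tie-break: among minimum-cost states prefer the one held by the
    # most tips (pushing changes toward the tips), then the smallest index
    tip_counts = np.zeros(K)
    for t in tree.tip_labels:
        tip_counts[idx[str(tip_states[t])]] += 1
    node_state = np.zeros(n_nodes, dtype=np.intp)
    for v in order:  # preorder: parents first
        p = tree.parent[v]
        if p < 0:
            cmin = cost[v].min()
            cand = np.flatnonzero(cost[v] == cmin)
            node_state[v] = int(cand[np.argmax(tip_counts[cand])])
        else:
            ps = node_state[p]
            score = cost[v] + (np.arange(K) != ps)
            best = score.min()
            if score[ps] == best:
                node_state[v] = ps
            else:
                node_state[v] = int(np.argmin(score))
    return RegimePainting(
        states=states,
        node_state=node_state,
        root_regime=int(node_state[tree.root]),
        change_count=change_count,
    )


def parsimony_minimum_bruteforce(
    tree: Phylogeny, tip_states: Mapping[str, str]
) -> int:
    """Exhaustive minimum change count over all internal labelings.

    Independent oracle for :func:`fitch_reconstruct`; feasible only for
    small trees (cost K**n_internal).
    """
    states = tuple(sorted({str(v) for v in tip_states.values()}))
    idx = {s: k for k, s in enumerate(states)}
    internals = [v for v in range(tree.n_nodes) if v >= tree.n_tips]
    tip_idx = np.array(
        [idx[str(tip_states[t])] for t in tree.tip_labels], dtype=np.intp
    )
    best = np.inf
    for lab in itertools.product(range(len(states)), repeat=len(internals)):
        assign = dict(zip(internals, lab))
        changes = 0
        for v in range(tree.n_nodes):
            p = tree.parent[v]
            if p < 0:
                continue
            sv = tip_idx[v] if v < tree.n_tips else assign[v]
            sp = assign[p]
            changes += sv != sp
        best = min(best, changes)
    return int(best)


def regime_weights(
    painting: RegimePainting, tree: Phylogeny, alpha: float
) -> RegimeWeightMatrix:
    """Optimum weights for every tip at selection strength ``alpha``.

    Requires a unit-height tree.  Each row sums to 1 exactly (telescoping);
    as ``alpha -> inf`` rows approach the indicator of the tip's own regime,
    as ``alpha -> 0`` the indicator of the root regime.
    """
    if not np.isfinite(alpha) or alpha <= 0:
        raise ValueError("alpha must be positive and finite (use the BM model otherwise)")
    tree.assert_ultrametric()
    T = tree.height
    if abs(T - 1.0) > 1e-6:
        raise ValueError(f"regime weights expect a unit-height tree (T={T:.6g})")
    n, K = tree.n_tips, painting.n_states
    depth = tree.depths()
    W = np.zeros((n, K))
    for i in range(n):
        W[i, painting.root_regime] += np.exp(-alpha * T)
        v = i
        while tree.parent[v] >= 0:
            p = tree.parent[v]
            k = painting.node_state[v]
            W[i, k] += np.exp(-alpha * (T - depth[v])) - np.exp(
                -alpha * (T - depth[p])
            )
            v = p
    return RegimeWeightMatrix(W=W, alpha=float(alpha), states=painting.states)
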