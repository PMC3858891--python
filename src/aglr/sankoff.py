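"""Generic minimum-cost labeling by dynamic programming (Sankoff-style).

Works on rooted trees of arbitrary arity and any distance exponent.  The
state space per node is {0} ∪ [g_min, g_max]: a classical consequence of the
distance axioms is that an optimal labeling never uses a positive label
outside the positive leaf-label range.

``sigma[k][i]`` is the minimal cost of the subtree rooted at node ``k`` given
that ``k`` is labeled ``i``.  Leaves are pinned to their observed length with
an infinite sentinel elsewhere.  For an internal node ``a`` with children
``b``:

    sigma_a(0) = sum_b min( sigma_b(0), C1 + min_j sigma_b(j) )
    sigma_a(i) = sum_b min( min_j [theta(i,j) + sigma_b(j)], C2 + sigma_b(0) )

The up phase costs O(|V| * m^2); the traceback recomputes argmins from the
stored table in O(m) per edge instead of storing back-pointers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .costs import LabelRange, PenaltyConfig, label_range
from .trees import RootedTree, TreeError

__all__ = [
    "CostTable",
    "dp_up",
    "min_total_cost",
    "traceback",
    "all_optimal_root_labels",
    "reconstruct_dp",
]

INF = math.inf


@dataclass
class CostTable:
    """Per-node conditional costs sigma.

    ``zero[k]`` is sigma_k(0); ``pos[k]`` is the vector of sigma_k(i) for
    ``i`` running over ``values`` (= g_min..g_max).  ``values`` is empty when
    every leaf is gene-absent.
    """

    tree: RootedTree
    config: PenaltyConfig
    rng: LabelRange
    values: np.ndarray
    zero: dict[int, float] = field(default_factory=dict)
    pos: dict[int, np.ndarray] = field(default_factory=dict)

    def sigma(self, node: int, label: int) -> float:
        """sigma_node(label); label must be 0 or inside [g_min, g_max]."""
        if label == 0:
            return self.zero[node]
        if self.rng.is_empty or not (self.rng.g_min <= label <= self.rng.g_max):
            raise ValueError(f"label {label} outside {{0}} ∪ [g_min, g_max]")
        return float(self.pos[node][label - self.rng.g_min])


def _distance_matrix(values: np.ndarray, lam) -> np.ndarray:
    diff = np.abs(values[:, None] - values[None, :]).astype(float)
    if lam == 1:
        return diff
    return diff**lam


def dp_up(
    tree: RootedTree, labels: dict[str, int], config: PenaltyConfig
) -> CostTable:
    """Postorder fill of the sigma table.

    ``labels`` maps leaf names to lengths; leaves missing from the mapping are
    treated as absent (0).  The all-absent case yields an empty positive range
    and a table whose only column is sigma(0).
    """
    leaf_value = {name: int(labels.get(name, 0)) for name in tree.leaf_names}
    if any(v < 0 for v in leaf_value.values()):
        raise ValueError("leaf lengths must be nonnegative")
    rng = label_range(leaf_value)
    values = (
        np.array([], dtype=int)
        if rng.is_empty
        else np.arange(rng.g_min, rng.g_max + 1)
    )
    m = len(values)
    D = _distance_matrix(values, config.lam) if m else np.zeros((0, 0))
    table = CostTable(tree=tree, config=config, rng=rng, values=values)

    for v in tree.postorder():
        if tree.is_leaf(v):
            p = leaf_value[tree.name(v)]
            row = np.full(m, INF)
            if p > 0:
                row[p - rng.g_min] = 0.0
            table.pos[v] = row
            table.zero[v] = 0.0 if p == 0 else INF
        else:
            zero_acc = 0.0
            pos_acc = np.zeros(m)
            for b in tree.children(v):
                zb, pb = table.zero[b], table.pos[b]
                best_pos_b = pb.min() if m else INF
                zero_acc += min(zb, config.c1 + best_pos_b)
                if m:
                    # min over child states j of theta(i, j) + sigma_b(j)
                    through = (D + pb[None, :]).min(axis=1)
                    pos_acc += np.minimum(through, config.c2 + zb)
            table.zero[v] = zero_acc
            table.pos[v] = pos_acc
    return table


def min_total_cost(table: CostTable) -> float:
    """S(G) = min over sigma_root(0) and sigma_root(i), i in [g_min, g_max]."""
    root = table.tree.root
    best = table.zero[root]
    if len(table.values):
        best = min(best, float(table.pos[root].min()))
    return _as_exact(best)


def all_optimal_root_labels(table: CostTable) -> set[int]:
    """All x in {0} ∪ [g_min, g_max] with sigma_root(x) == S(G)."""
    root = table.tree.root
    best = min_total_cost(table)
    out: set[int] = set()
    if table.zero[root] == best:
        out.add(0)
    if len(table.values):
        out.update(int(x) for x in table.values[table.pos[root] == best])
    return out


def traceback(
    tree: RootedTree, table: CostTable, config: PenaltyConfig
) -> dict[int, int]:
    """Preorder reconstruction of one optimal labeling.

    Deterministic tie policy: at the root, a positive label is preferred over
    0 when their sigma values tie, and the smallest optimal positive label is
    taken; below the root, the positive branch is preferred on ties against
    the zero branch when the parent is positive (zero preferred when the
    parent is 0), and among tied positive labels the one nearest the parent's
    label, then the smallest, wins.  Every choice attains the same total cost.
    """
    m = len(table.values)
    D = _distance_matrix(table.values, config.lam) if m else None
    labels: dict[int, int] = {}
    root = tree.root

    best_pos = float(table.pos[root].min()) if m else INF
    if m and best_pos <= table.zero[root]:
        labels[root] = int(table.values[np.argmax(table.pos[root] == best_pos)])
    else:
        labels[root] = 0

    for v in tree.preorder():
        parent_label = labels[v]
        for b in tree.children(v):
            if tree.is_leaf(b):
                if table.zero[b] == 0.0:
                    labels[b] = 0
                else:
                    labels[b] = int(table.values[np.argmin(table.pos[b])])
                continue
            zb, pb = table.zero[b], table.pos[b]
            if parent_label > 0:
                i = parent_label - table.rng.g_min
                through = D[i] + pb
                best_pos = float(through.min())
                if best_pos <= config.c2 + zb:
                    labels[b] = _pick_nearest(table.values, through, best_pos, parent_label)
                else:
                    labels[b] = 0
            else:
                gain = config.c1 + (float(pb.min()) if m else INF)
                if zb <= gain:
                    labels[b] = 0
                else:
                    best = float(pb.min())
                    labels[b] = _pick_nearest(table.values, pb, best, 0)
    return labels


def _pick_nearest(values: np.ndarray, costs: np.ndarray, best: float, target: int) -> int:
    cands = values[costs == best]
    order = np.lexsort((cands, np.abs(cands - target)))
    return int(cands[order[0]])


def reconstruct_dp(
    tree: RootedTree, labels: dict[str, int], config: PenaltyConfig
) -> tuple[dict[int, int], float, CostTable]:
    """Convenience wrapper: up phase + traceback + minimum cost."""
    if not tree.internal_nodes() and tree.n_leaves != 1:
        raise TreeError("tree has no internal nodes")
    table = dp_up(tree, labels, config)
    labeling = traceback(tree, table, config)
    return labeling, min_total_cost(table), table


def _as_exact(x: float) -> float | int:
    """Report integral costs as ints (lam=1 with integer penalties is exact)."""
    if math.isfinite(x) and float(x).is_integer():
        return int(x)
    return x
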