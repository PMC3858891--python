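"""Brute-force exhaustive minimiser — ground truth for small instances.

Enumerates every assignment of {0} ∪ [g_min, g_max] to the internal nodes
and takes the cheapest, independent of any dynamic-programming machinery.
The positive-label domain may be widened (``widen``) to verify empirically
that optima never use labels outside the standard range.

The full cost tensor over the d^k assignment grid (d = domain size, k =
internal nodes) is materialised with numpy broadcasting, so the practical
limit is the ``cap`` on grid size, not Python-loop speed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .costs import PenaltyConfig, label_range
from .trees import RootedTree

__all__ = ["OracleResult", "exhaustive_min"]


@dataclass
class OracleResult:
    cost: int | float
    n_optimal: int
    labeling: dict[int, int]
    optimal_root_labels: set[int]


def exhaustive_min(
    tree: RootedTree,
    labels: dict[str, int],
    config: PenaltyConfig,
    cap: int = 10_000_000,
    widen: int = 0,
) -> OracleResult:
    """Exact global minimum of the total edge cost by enumeration.

    ``cap`` bounds the assignment-grid size d**k; exceeding it raises with
    advice to shrink the instance.  ``widen`` extends the positive domain by
    that many units on each side (clipped at 1), for range-restriction
    checks.
    """
    leaf_value = {name: int(labels.get(name, 0)) for name in tree.leaf_names}
    rng = label_range(leaf_value)
    if rng.is_empty:
        domain = np.array([0])
    else:
        lo = max(1, rng.g_min - widen)
        hi = rng.g_max + widen
        domain = np.concatenate(([0], np.arange(lo, hi + 1)))
    internal = tree.internal_nodes()
    k = len(internal)
    d = len(domain)
    if k and d**k > cap:
        raise ValueError(
            f"oracle grid {d}^{k} exceeds cap {cap}; use a smaller instance"
        )
    axis = {v: i for i, v in enumerate(internal)}
    shape = (d,) * k if k else (1,)
    total = np.zeros(shape)

    def phi_vector(p_fixed: int) -> np.ndarray:
        """phi(x, p_fixed) for x over the domain (parent varies)."""
        return np.array([_phi(x, p_fixed, config) for x in domain])

    def phi_matrix() -> np.ndarray:
        return np.array([[_phi(x, y, config) for y in domain] for x in domain])

    M = phi_matrix() if k else None
    for v in tree.preorder():
        for b in tree.children(v):
            if tree.is_leaf(b):
                vec = phi_vector(leaf_value[tree.name(b)])
                total += _along_axis(vec, axis[v], k)
            else:
                total += _along_axes(M, axis[v], axis[b], k)

    best = float(total.min())
    mask = total == best
    n_opt = int(mask.sum())
    flat = int(np.argmin(total))
    idx = np.unravel_index(flat, shape) if k else (0,)
    labeling = {v: int(domain[idx[axis[v]]]) for v in internal}
    for leaf in tree.leaves:
        labeling[leaf] = leaf_value[tree.name(leaf)]
    if tree.root in axis:
        root_axis = axis[tree.root]
        other = tuple(i for i in range(k) if i != root_axis)
        root_hits = mask.any(axis=other) if other else mask
        root_labels = {int(x) for x in domain[root_hits]}
    else:  # single-leaf tree: the root is the leaf itself
        root_labels = {leaf_value[tree.name(tree.root)]}
    if best.is_integer():
        best = int(best)
    return OracleResult(best, n_opt, labeling, root_labels)


def _phi(x: int, y: int, config: PenaltyConfig) -> float:
    if x == y:
        return 0.0
    if x == 0:
        return float(config.c1)
    if y == 0:
        return float(config.c2)
    return float(abs(x - y) ** config.lam)


def _along_axis(vec: np.ndarray, ax: int, k: int) -> np.ndarray:
    shape = [1] * max(k, 1)
    shape[ax] = len(vec)
    return vec.reshape(shape)


def _along_axes(mat: np.ndarray, ax_row: int, ax_col: int, k: int) -> np.ndarray:
    # broadcastable view with the row index on ax_row and column on ax_col;
    # C-order flattening requires the earlier axis to vary slowest
    shape = [1] * k
    shape[ax_row] = mat.shape[0]
    shape[ax_col] = mat.shape[1]
    if ax_row < ax_col:
        return mat.reshape(shape)
    return np.ascontiguousarray(mat.T).reshape(shape)
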