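"""Synthetic instances: forward gain/loss/drift simulation and worked fixtures.

Two generators are provided:

* :func:`simulate_instance` — a forward model over a random rooted tree.  A
  present gene is lost along an edge with probability ``loss_prob``, an
  absent gene is (re)gained with probability ``gain_prob``, and a surviving
  gene drifts by a bounded uniform integer step.  The true internal labels
  are returned alongside the leaf observations, for recovery experiments.

* :func:`random_leaf_instance` — direct leaf-label sampling (each leaf absent
  with a fixed probability, else uniform in a narrow window) together with
  penalties drawn to respect C1 > C2 > m.  This is the workhorse of the
  cross-algorithm equivalence checks.

:func:`worked_examples` ships the small worked examples used throughout the
documentation and tests: two- to four-leaf trees with lengths drawn from
{125, 136, 141, 150} under penalties C1=50, C2=30, and the chemotaxis-family
(COG0835) archaeal paralog length table keyed by genome number.  Expected
values carry provenance tags.  The "fig4-candidate" fixture is a plausible
but unverified topology for the published "peculiar tree" example, whose
exact shape is not fully recoverable; it is marked accordingly and excluded
from exact-value tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .costs import PenaltyConfig
from .trees import RootedTree, parse_newick

__all__ = [
    "SimConfig",
    "random_tree",
    "simulate_instance",
    "random_leaf_instance",
    "Fixture",
    "worked_examples",
    "get_fixture",
]


@dataclass(frozen=True)
class SimConfig:
    """Forward-model parameters.

    Defaults describe a moderately volatile single-copy gene family: the gene
    is present at the root with a length around 150 residues, losses are
    somewhat more likely than gains (per-edge 0.15 vs 0.05), and a surviving
    gene drifts by at most 3 residues per edge.
    """

    n_leaves: int = 8
    seed: int = 0
    binary: bool = True
    max_arity: int = 4
    gain_prob: float = 0.05
    loss_prob: float = 0.15
    drift_max_step: int = 3
    root_length: tuple[int, int] = (140, 160)  # (lo, hi) sampled uniformly; (0, 0) = absent root
    min_length: int = 2  # drift floor; a drifting gene never reaches 0 by drift alone

    def __post_init__(self) -> None:
        if not 0 <= self.gain_prob <= 1 or not 0 <= self.loss_prob <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_leaves < 1:
            raise ValueError("need at least one leaf")
        if self.drift_max_step < 0:
            raise ValueError("drift step must be nonnegative")


def random_tree(
    rng: np.random.Generator, n_leaves: int, binary: bool = True, max_arity: int = 4
) -> RootedTree:
    """Random rooted tree by repeatedly merging subtrees.

    ``binary`` merges pairs; otherwise merge groups of 2..max_arity, yielding
    multifurcations.
    """
    names = {i: f"L{i + 1}" for i in range(n_leaves)}
    children: dict[int, list[int]] = {}
    roots = list(range(n_leaves))
    next_id = n_leaves
    while len(roots) > 1:
        take = 2 if binary else int(rng.integers(2, min(max_arity, len(roots)) + 1))
        picks = rng.choice(len(roots), size=take, replace=False)
        kids = [roots[i] for i in sorted(picks, reverse=True)]
        for i in sorted(picks, reverse=True):
            del roots[i]
        children[next_id] = kids
        roots.append(next_id)
        next_id += 1
    return RootedTree(children, names, roots[0])


def simulate_instance(
    config: SimConfig,
) -> tuple[RootedTree, dict[int, int], dict[str, int]]:
    """Evolve a gene length down a random tree.

    Returns ``(tree, true labeling by node id, leaf lengths by name)``.
    Deterministic for a fixed config (the seed is part of the config).
    """
    rng = np.random.default_rng(config.seed)
    tree = random_tree(rng, config.n_leaves, binary=config.binary, max_arity=config.max_arity)
    lo, hi = config.root_length
    state: dict[int, int] = {}
    if lo <= 0 and hi <= 0:
        state[tree.root] = 0
    else:
        state[tree.root] = int(rng.integers(lo, hi + 1))
    if config.gain_prob == 0 and state[tree.root] == 0:
        import warnings

        warnings.warn("root absent with zero gain probability: all labels will be 0")
    for v in tree.preorder():
        for b in tree.children(v):
            s = state[v]
            if s == 0:
                if rng.random() < config.gain_prob:
                    glo = max(config.min_length, lo)
                    ghi = max(glo, hi)
                    s = int(rng.integers(glo, ghi + 1))
            else:
                if rng.random() < config.loss_prob:
                    s = 0
                elif config.drift_max_step > 0:
                    step = int(rng.integers(-config.drift_max_step, config.drift_max_step + 1))
                    s = max(config.min_length, s + step)
            state[b] = s
    leaf_lengths = {tree.name(v): state[v] for v in tree.leaves}
    return tree, state, leaf_lengths


def random_leaf_instance(
    rng: np.random.Generator,
    max_leaves: int = 16,
    absent_prob: float = 0.25,
    max_window: int = 10,
    binary: bool = True,
    max_arity: int = 4,
) -> tuple[RootedTree, dict[str, int], PenaltyConfig]:
    """Direct leaf sampling for cross-algorithm equivalence checks.

    Each leaf is absent with probability ``absent_prob``, otherwise uniform
    in an integer window of width <= ``max_window``.  Penalties are drawn to
    respect C1 > C2 > m for the realised range.
    """
    n = int(rng.integers(2, max_leaves + 1))
    tree = random_tree(rng, n, binary=binary, max_arity=max_arity)
    base = int(rng.integers(5, 200))
    width = int(rng.integers(1, max_window + 1))
    labels: dict[str, int] = {}
    for name in tree.leaf_names:
        if rng.random() < absent_prob:
            labels[name] = 0
        else:
            labels[name] = base + int(rng.integers(0, width))
    positive = [v for v in labels.values() if v > 0]
    m = (max(positive) - min(positive) + 1) if positive else 1
    c2 = m + 1 + int(rng.integers(0, 20))
    c1 = c2 + 1 + int(rng.integers(0, 30))
    return tree, labels, PenaltyConfig(c1=c1, c2=c2, lam=1)


@dataclass(frozen=True)
class Fixture:
    """A named worked example with provenance-tagged expectations."""

    name: str
    newick: str
    lengths: dict[str, int]
    config: PenaltyConfig
    expected: dict[str, Any] = field(default_factory=dict)
    note: str = ""

    def tree(self) -> RootedTree:
        return parse_newick(self.newick)


_STD = PenaltyConfig(c1=50, c2=30, lam=1)

#: Archaeal chemotaxis-protein (COG0835) copy lengths, keyed by genome number.
COG0835_PARALOGS: dict[str, list[int]] = {
    "1": [160],
    "29": [144, 328],
    "30": [132, 178],
    "31": [132, 178],
    "39": [159],
    "41": [146],
    "42": [146],
    "43": [146],
    "44": [147],
    "46": [182, 184],
    "47": [173],
    "48": [159, 189],
    "50": [124, 167, 169, 169, 174, 176, 183, 187, 189, 190, 198, 200, 344, 779],
}


def worked_examples() -> list[Fixture]:
    """The small worked examples (two- to four-leaf trees, C1=50, C2=30)."""
    return [
        Fixture(
            "fig1a",
            "(A,B);",
            {"A": 0, "B": 0},
            _STD,
            expected={"cost": ("trivial", 0), "root_label": ("published", 0)},
            note="no genes at the leaves, none at the root",
        ),
        Fixture(
            "fig1b",
            "(A,B);",
            {"A": 0, "B": 136},
            _STD,
            expected={"cost": ("published", 30), "root_label": ("published", 136)},
            note="single present leaf: root keeps the gene, one loss (C2=30)",
        ),
        Fixture(
            "fig1c",
            "(A,B);",
            {"A": 125, "B": 136},
            _STD,
            expected={
                "cost": ("published", 11),
                "optimal_root_labels": ("published", set(range(125, 137))),
            },
            note="any root label in [125, 136]; cost 136-125=11",
        ),
        Fixture(
            "fig2a",
            "(Z,(A,B));",
            {"Z": 0, "A": 125, "B": 136},
            _STD,
            expected={
                "cost": ("derived", 41),
                "root_label_smallest": ("published", 125),
                "sigma_root_zero": ("derived", 61),
            },
            note="root positive (X=C2+11=41 beats Z=C1+11=61), smallest pick 125",
        ),
        Fixture(
            "fig2c",
            "((A,B),C);",
            {"A": 125, "B": 136, "C": 141},
            _STD,
            expected={
                "cost": ("derived", 16),
                "root_label": ("published", 136),
                "root_interval": ("derived", (136, 141)),
            },
            note="disjoint child intervals [125,136] and [141,141]; gap interval",
        ),
        Fixture(
            "fig3",
            "((A,B),(C,D));",
            {"A": 125, "B": 141, "C": 136, "D": 150},
            _STD,
            expected={
                "cost": ("derived", 30),
                "optimal_root_labels": ("published", set(range(136, 142))),
                "root_label_shown": ("published", 136),
            },
            note="root interval [125,141] ∩ [136,150] = [136,141]",
        ),
        Fixture(
            "fig4-candidate",
            "((((Z1,Z2),Z3),P),(Z4,(A,B)));",
            {"Z1": 0, "Z2": 0, "Z3": 0, "P": 136, "Z4": 0, "A": 125, "B": 136},
            _STD,
            expected={},
            note=(
                "UNVERIFIED synthetic stand-in: the published 'peculiar tree' "
                "topology is only partially recoverable, so this candidate "
                "carries no trusted expected values; only the DP/interval "
                "equivalence property applies"
            ),
        ),
    ]


def get_fixture(name: str) -> Fixture:
    for fx in worked_examples():
        if fx.name == name:
            return fx
    raise KeyError(
        f"unknown fixture {name!r}; available: {[f.name for f in worked_examples()]}"
    )
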