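"""Evolutionary-scenario reporting: classify each edge of a labeled tree.

A complete labeling induces one event per directed edge parent → child:
``gain`` (0 → k), ``loss`` (k → 0), ``elongation`` / ``shortening`` (both
positive, Manhattan runs), ``change`` (both positive, lam != 1), or ``none``.
The audited total

    S = sum of |parent - child| over doubly-positive edges + k1*C1 + k2*C2

(with k1 gains and k2 losses) must equal the cost reported by whichever
algorithm produced the labeling; the audit is the package's core internal
consistency check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .costs import PenaltyConfig, edge_cost
from .trees import RootedTree, TreeError

log = logging.getLogger(__name__)

__all__ = ["EdgeEvent", "Scenario", "annotate", "audit"]


@dataclass(frozen=True)
class EdgeEvent:
    parent: int
    child: int
    parent_label: int
    child_label: int
    event: str
    cost: int | float


@dataclass
class Scenario:
    """Per-edge events plus totals (k1 gains, k2 losses, length change, S)."""

    events: list[EdgeEvent] = field(default_factory=list)
    k1: int = 0
    k2: int = 0
    change_total: int | float = 0
    total_cost: int | float = 0

    def to_frame(self, tree: RootedTree | None = None) -> pd.DataFrame:
        rows = []
        for e in self.events:
            rows.append(
                {
                    "parent_id": tree.name(e.parent) or e.parent if tree else e.parent,
                    "child_id": tree.name(e.child) or e.child if tree else e.child,
                    "parent_label": e.parent_label,
                    "child_label": e.child_label,
                    "event": e.event,
                    "cost": e.cost,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "parent_id",
                "child_id",
                "parent_label",
                "child_label",
                "event",
                "cost",
            ],
        )

    def summary(self) -> str:
        return (
            f"gains k1={self.k1}, losses k2={self.k2}, "
            f"length change={self.change_total}, total cost={self.total_cost}"
        )


def _classify(p: int, c: int, lam) -> str:
    if p == c:
        return "none"
    if p == 0:
        return "gain"
    if c == 0:
        return "loss"
    if lam != 1:
        return "change"
    return "elongation" if c > p else "shortening"


def annotate(
    tree: RootedTree, labeling: Mapping[int, int], config: PenaltyConfig
) -> Scenario:
    """Classify every edge of a completely labeled tree."""
    missing = [v for v in tree.nodes if v not in labeling]
    if missing:
        raise TreeError(f"labeling incomplete: missing nodes {sorted(missing)}")
    sc = Scenario()
    for v in tree.preorder():
        p = int(labeling[v])
        for b in tree.children(v):
            c = int(labeling[b])
            cost = edge_cost(p, c, config)
            event = _classify(p, c, config.lam)
            sc.events.append(EdgeEvent(v, b, p, c, event, cost))
            if event == "gain":
                sc.k1 += 1
            elif event == "loss":
                sc.k2 += 1
            else:
                sc.change_total += cost
            sc.total_cost += cost
    return sc


def audit(scenario: Scenario, reported_cost: int | float) -> bool:
    """True iff the scenario total equals the algorithm's reported cost.

    On mismatch the per-edge decomposition is logged to ease debugging.
    """
    if scenario.total_cost == reported_cost:
        return True
    log.error(
        "audit mismatch: scenario total %s != reported %s\n%s",
        scenario.total_cost,
        reported_cost,
        "\n".join(
            f"  {e.parent}->{e.child}: {e.parent_label}->{e.child_label} "
            f"{e.event} cost={e.cost}"
            for e in scenario.events
        ),
    )
    return False
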