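"""High-level reconstruction entry point shared by the library API and CLI."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

from . import interval as interval_mod
from . import sankoff
from .costs import LabelRange, PenaltyConfig, label_range, validate_penalties
from .scenario import Scenario, annotate, audit
from .trees import RootedTree, align_lengths

log = logging.getLogger(__name__)

__all__ = ["Reconstruction", "reconstruct"]


class AuditError(RuntimeError):
    """The scenario total disagreed with the algorithm's reported cost."""


@dataclass
class Reconstruction:
    """Outcome of one reconstruction run."""

    tree: RootedTree
    labeling: dict[int, int]
    cost: int | float
    method: str
    config: PenaltyConfig
    rng: LabelRange
    scenario: Scenario
    quartets: dict[int, interval_mod.Quartet] | None = None
    corrected: dict[int, interval_mod.Interval] | None = None
    table: sankoff.CostTable | None = None
    warnings: list[str] = field(default_factory=list)

    def labeled_newick(self) -> str:
        return self.tree.to_newick(labels=self.labeling)


def reconstruct(
    tree: RootedTree,
    lengths: Mapping[str, int],
    config: PenaltyConfig,
    method: str = "interval",
    root_pick: str = "smallest",
    strict_lengths: bool = False,
) -> Reconstruction:
    """Reconstruct ancestral gene lengths and audit the result.

    ``method`` is ``"interval"`` (binary trees, Manhattan distance, linear
    time) or ``"dp"`` (arbitrary arity and distance exponent).  The returned
    labeling's edge-by-edge cost is always re-derived and compared with the
    algorithm's reported minimum; a mismatch raises :class:`AuditError`.
    """
    labels = align_lengths(tree, lengths, strict=strict_lengths)
    rng = label_range(labels)
    issues = validate_penalties(config, rng)
    quartets = corrected = table = None
    if rng.is_empty:
        labeling = {v: 0 for v in tree.nodes}
        cost: int | float = 0
        if method == "interval":
            quartets = interval_mod.bottom_up(tree, labels, config)
            corrected = interval_mod.correct_intervals(tree, quartets, config)
    elif method == "dp":
        labeling, cost, table = sankoff.reconstruct_dp(tree, labels, config)
    elif method == "interval":
        labeling, cost, quartets, corrected = interval_mod.reconstruct_interval(
            tree, labels, config, root_pick=root_pick
        )
    else:
        raise ValueError(f"unknown method {method!r}; choose 'dp' or 'interval'")
    sc = annotate(tree, labeling, config)
    if not audit(sc, cost):
        raise AuditError(
            f"scenario total {sc.total_cost} != reported minimum {cost} "
            f"(method={method})"
        )
    log.info(
        "reconstructed (%s): C1=%s C2=%s lam=%s range=[%s,%s] m=%s  %s",
        method,
        config.c1,
        config.c2,
        config.lam,
        "-" if rng.is_empty else rng.g_min,
        "-" if rng.is_empty else rng.g_max,
        rng.m,
        sc.summary(),
    )
    return Reconstruction(
        tree=tree,
        labeling=labeling,
        cost=cost,
        method=method,
        config=config,
        rng=rng,
        scenario=sc,
        quartets=quartets,
        corrected=corrected,
        table=table,
        warnings=issues,
    )
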