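"""Edge-cost model: gain/loss penalties and the length-change distance family.

An edge between labels ``x`` (parent side) and ``y`` (child side) costs

* 0 when ``x == y`` (in particular 0→0),
* the gain penalty ``C1`` when ``x == 0`` and ``y > 0`` (gene birth),
* the loss penalty ``C2`` when ``x > 0`` and ``y == 0`` (gene death),
* otherwise the length-change distance ``theta(x, y) = |x - y|**lam``.

The modeling convention is ``C1 > C2 > m`` with ``m = g_max - g_min + 1`` the
width of the positive leaf-label range: a loss is cheaper than a gain, and
either event is dearer than any pure length change.  The recurrences remain
well defined when the inequality fails, so violations warn rather than error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from numbers import Real
from typing import Mapping

__all__ = [
    "PenaltyConfig",
    "LabelRange",
    "theta",
    "edge_cost",
    "label_range",
    "validate_penalties",
]


@dataclass(frozen=True)
class PenaltyConfig:
    """Gain penalty ``c1``, loss penalty ``c2`` and distance exponent ``lam``.

    ``lam`` must be >= 1; ``lam == 1`` is the Manhattan preset required by the
    interval algorithm, ``lam == 2`` the squared-difference preset.
    """

    c1: int | float
    c2: int | float
    lam: int | float = 1

    def __post_init__(self) -> None:
        if not isinstance(self.c1, Real) or not isinstance(self.c2, Real):
            raise TypeError("penalties must be numbers")
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("penalties C1 and C2 must be positive")
        if self.lam < 1:
            raise ValueError("distance exponent lam must be >= 1")


@dataclass(frozen=True)
class LabelRange:
    """Range [g_min, g_max] of the positive leaf labels; m = g_max - g_min + 1.

    ``is_empty`` marks the all-absent case (no positive leaf label at all).
    """

    g_min: int
    g_max: int
    is_empty: bool = False

    @property
    def m(self) -> int:
        return 0 if self.is_empty else self.g_max - self.g_min + 1

    @classmethod
    def empty(cls) -> "LabelRange":
        return cls(0, 0, is_empty=True)


def theta(x: int, y: int, lam: int | float = 1):
    """Length-change distance |x - y|**lam between two *positive* labels.

    Zero labels never reach theta — the gain/loss branches of
    :func:`edge_cost` intercept them first.
    """
    if x < 1 or y < 1:
        raise ValueError("theta is defined for positive labels only")
    d = abs(x - y)
    if lam == 1:
        return d
    return d**lam


def edge_cost(x: int, y: int, config: PenaltyConfig):
    """Cost of the directed edge parent-label ``x`` → child-label ``y``."""
    if x < 0 or y < 0:
        raise ValueError("labels must be nonnegative")
    if x == y:
        return 0
    if x == 0:
        return config.c1
    if y == 0:
        return config.c2
    return theta(x, y, config.lam)


def label_range(labels: Mapping[str, int]) -> LabelRange:
    """Positive-label range of a leaf table; empty flag when all labels are 0."""
    positive = [int(v) for v in labels.values() if v > 0]
    if any(v < 0 for v in labels.values()):
        raise ValueError("leaf lengths must be nonnegative")
    if not positive:
        return LabelRange.empty()
    return LabelRange(min(positive), max(positive))


def validate_penalties(config: PenaltyConfig, rng: LabelRange) -> list[str]:
    """Check the modeling inequality ``C1 > C2 > m``.

    Returns the list of diagnostics (empty when all is well) and emits each as
    a :class:`UserWarning`.  Nonpositive penalties are rejected at
    :class:`PenaltyConfig` construction already; re-checked here defensively.
    """
    if config.c1 <= 0 or config.c2 <= 0:
        raise ValueError("penalties C1 and C2 must be positive")
    issues: list[str] = []
    if config.c1 <= config.c2:
        issues.append(f"C1 <= C2 ({config.c1} <= {config.c2}): gain not dearer than loss")
    if not rng.is_empty and config.c2 <= rng.m:
        issues.append(
            f"C2 <= m ({config.c2} <= {rng.m}): loss not dearer than the widest "
            "length change; interval-algorithm optimality guarantees assume C2 > m"
        )
    for msg in issues:
        warnings.warn(msg, UserWarning, stacklevel=2)
    return issues
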