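"""Collapse per-genome paralog length lists to a single leaf label.

Real gene families often carry several paralogous copies per genome; the
labeling model wants one integer per leaf.  The convention here is the median
of the copy lengths (lower median for even counts, so the label is always an
observed length), optionally after flagging outlying copies — e.g. fusion
proteins several-fold longer than the family norm.

Outlier flagging is report-only by default; removal requires explicit
opt-in, mirroring how such values are normally excised by inspection.
Policies:

* ``mad`` (default): modified z-score 0.6745 * |x - median| / MAD > 3.5,
  needs at least 3 values;
* ``ratio``: for two-value genomes, flag the larger value when it exceeds
  1.8x the smaller;
* ``none``: flag nothing.
"""

from __future__ import annotations

import io
from statistics import median as _true_median
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "read_paralog_table",
    "median_label",
    "flag_outliers",
    "collapse_paralogs",
]

OUTLIER_POLICIES = ("none", "mad", "ratio")


def read_paralog_table(source: str | io.TextIOBase) -> dict[str, list[int]]:
    """Read a ``leaf<TAB>length`` table with repeated leaves allowed."""
    if isinstance(source, str) and "\t" not in source and "\n" not in source:
        with open(source) as fh:
            return read_paralog_table(fh)
    if isinstance(source, str):
        source = io.StringIO(source)
    frame = pd.read_csv(source, sep="\t", header=None, comment="#", dtype=str)
    if frame.shape[1] < 2:
        raise ValueError("paralog table needs two tab-separated columns")
    frame = frame.iloc[:, :2]
    frame.columns = ["leaf", "length"]
    if frame.iloc[0]["leaf"].strip().lower() == "leaf":
        frame = frame.iloc[1:]
    out: dict[str, list[int]] = {}
    for _, row in frame.iterrows():
        name = str(row["leaf"]).strip()
        value = int(str(row["length"]).strip())
        if value <= 0:
            raise ValueError(f"paralog lengths must be positive (leaf {name!r}: {value})")
        out.setdefault(name, []).append(value)
    return out


def median_label(lengths: Iterable[int]) -> int:
    """Single leaf label from a multiset of copy lengths.

    Empty → 0 (gene absent).  Odd count → middle order statistic.  Even count
    → lower median, so the label is always one of the observed lengths.
    """
    values = sorted(int(v) for v in lengths)
    if not values:
        return 0
    if any(v <= 0 for v in values):
        raise ValueError("paralog lengths must be positive")
    return values[(len(values) - 1) // 2]


def flag_outliers(lengths: Iterable[int], rule: str = "mad") -> list[int]:
    """Return the values flagged as outliers under the chosen policy.

    Statistical flagging needs at least 3 values (``mad``); the ``ratio``
    policy covers two-value genomes.  Nothing is ever flagged when all values
    are equal.
    """
    values = sorted(int(v) for v in lengths)
    if rule not in OUTLIER_POLICIES:
        raise ValueError(f"unknown outlier policy {rule!r}; choose from {OUTLIER_POLICIES}")
    if rule == "none" or len(values) < 2 or len(set(values)) == 1:
        return []
    if rule == "ratio":
        if len(values) == 2 and values[1] > 1.8 * values[0]:
            return [values[1]]
        return []
    # modified z-score on the raw lengths
    if len(values) < 3:
        return []
    med = _true_median(values)
    mad = _true_median([abs(v - med) for v in values])
    if mad == 0:
        return []
    return [v for v in values if 0.6745 * abs(v - med) / mad > 3.5]


def collapse_paralogs(
    table: Mapping[str, list[int]],
    outlier_policy: str = "mad",
    drop_outliers: bool = False,
) -> tuple[dict[str, int], dict[str, list[int]]]:
    """Reduce a paralog table to leaf labels.

    Returns ``(labels, flagged)`` where ``flagged`` maps each leaf to the
    values its policy marked.  Flagged values are excluded from the median
    only when ``drop_outliers`` is set; should removal empty a leaf's list,
    the original values are kept (removal never silently deletes a gene).
    """
    labels: dict[str, int] = {}
    flagged: dict[str, list[int]] = {}
    for leaf, values in table.items():
        marks = flag_outliers(values, rule=outlier_policy)
        if marks:
            flagged[leaf] = marks
        kept = list(values)
        if drop_outliers and marks:
            remaining = list(kept)
            for v in marks:
                if v in remaining:
                    remaining.remove(v)
            if remaining:
                kept = remaining
        labels[leaf] = median_label(kept)
    return labels, flagged
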