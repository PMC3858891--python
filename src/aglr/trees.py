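"""Rooted-tree data model and I/O for Newick trees and leaf-length tables.

The tree model is deliberately minimal: integer node ids, ordered children,
string names on leaves (and optionally on internal nodes).  Branch lengths in
Newick input are accepted and discarded — the cost model is per edge, not per
unit time.  Gene lengths live in a separate ``{leaf name: int}`` mapping in
which the value 0 means "gene absent".
"""

from __future__ import annotations

import io
import logging
from typing import Iterable, Iterator, Mapping

import dendropy
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "TreeError",
    "NewickParseError",
    "RootedTree",
    "parse_newick",
    "read_leaf_lengths",
    "align_lengths",
    "write_labeled_newick",
]


class TreeError(ValueError):
    """Structural problem with a tree or a labeling."""


class NewickParseError(TreeError):
    """Malformed Newick input."""


class RootedTree:
    """A rooted tree with ordered children and named leaves.

    Parameters
    ----------
    children:
        Mapping from node id to the ordered list of child ids.  Nodes that do
        not appear as keys (or map to an empty list) are leaves.
    names:
        Mapping from node id to a display name.  Every leaf must have a
        nonempty, unique name; internal names are optional and are preserved
        for reporting only.
    root:
        Id of the root node.
    """

    def __init__(
        self,
        children: Mapping[int, Iterable[int]],
        names: Mapping[int, str],
        root: int,
    ) -> None:
        self._children: dict[int, list[int]] = {
            int(k): [int(c) for c in v] for k, v in children.items()
        }
        self._names: dict[int, str] = {int(k): str(v) for k, v in names.items()}
        self.root = int(root)
        self._parent: dict[int, int | None] = {}
        self._validate()

    # -- construction helpers -------------------------------------------------

    def _validate(self) -> None:
        parent: dict[int, int | None] = {self.root: None}
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            for c in self._children.get(v, []):
                if c in parent:
                    raise TreeError(f"node {c} has more than one parent (or a cycle)")
                parent[c] = v
                stack.append(c)
        known = set(parent)
        mentioned = set(self._children) | {
            c for kids in self._children.values() for c in kids
        } | {self.root}
        if mentioned - known:
            raise TreeError(f"nodes unreachable from the root: {sorted(mentioned - known)}")
        self._parent = parent
        self._nodes = order
        leaves = [v for v in order if not self._children.get(v)]
        seen: set[str] = set()
        for v in leaves:
            name = self._names.get(v, "")
            if not name:
                raise TreeError(f"leaf node {v} has no name")
            if name in seen:
                raise TreeError(f"duplicate leaf name {name!r}")
            seen.add(name)
        self._leaves = leaves

    # -- basic accessors ------------------------------------------------------

    @property
    def nodes(self) -> list[int]:
        """All node ids (root first, otherwise unspecified order)."""
        return list(self._nodes)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def leaves(self) -> list[int]:
        return list(self._leaves)

    @property
    def n_leaves(self) -> int:
        return len(self._leaves)

    @property
    def leaf_names(self) -> list[str]:
        return [self._names[v] for v in self._leaves]

    def children(self, v: int) -> list[int]:
        return list(self._children.get(v, []))

    def parent(self, v: int) -> int | None:
        return self._parent[v]

    def name(self, v: int) -> str:
        return self._names.get(v, "")

    def is_leaf(self, v: int) -> bool:
        return not self._children.get(v)

    def is_binary(self) -> bool:
        """True when every internal node has exactly two children."""
        return all(
            len(self._children.get(v, [])) == 2
            for v in self._nodes
            if not self.is_leaf(v)
        )

    def internal_nodes(self) -> list[int]:
        return [v for v in self._nodes if not self.is_leaf(v)]

    # -- traversals -----------------------------------------------------------

    def postorder(self) -> Iterator[int]:
        """Children before parents (iterative; no recursion limit)."""
        stack: list[tuple[int, bool]] = [(self.root, False)]
        while stack:
            v, expanded = stack.pop()
            if expanded or self.is_leaf(v):
                yield v
            else:
                stack.append((v, True))
                for c in reversed(self._children[v]):
                    stack.append((c, False))

    def preorder(self) -> Iterator[int]:
        """Parents before children."""
        stack = [self.root]
        while stack:
            v = stack.pop()
            yield v
            for c in reversed(self._children.get(v, [])):
                stack.append(c)

    # -- derived trees --------------------------------------------------------

    def with_child_order(self, children: Mapping[int, Iterable[int]]) -> "RootedTree":
        """Same tree with children permuted (used by invariance tests)."""
        return RootedTree(children, self._names, self.root)

    # -- Newick output --------------------------------------------------------

    def to_newick(self, labels: Mapping[int, int] | None = None) -> str:
        """Render as Newick.

        With ``labels``, each internal node carries its integer label in the
        internal-name slot, e.g. ``(A,B)130;``.  Leaves always carry their
        names only — their labels are the input lengths.
        """

        def render(v: int) -> str:
            if self.is_leaf(v):
                return _quote(self._names[v])
            inner = ",".join(render(c) for c in self._children[v])
            if labels is not None:
                tag = str(int(labels[v]))
            else:
                tag = _quote(self._names.get(v, "")) if self._names.get(v) else ""
            return f"({inner}){tag}"

        if labels is not None:
            missing = [v for v in self.nodes if v not in labels]
            if missing:
                raise TreeError(f"labeling incomplete: missing nodes {sorted(missing)}")
        return render(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"RootedTree(n_leaves={self.n_leaves}, n_nodes={self.n_nodes})"


def _quote(name: str) -> str:
    if any(ch in name for ch in "(),:;[] \t'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def parse_newick(text: str) -> RootedTree:
    """Parse a Newick string into a :class:`RootedTree`.

    Child order is preserved, branch lengths are discarded, and internal-node
    labels are kept as names.  Raises :class:`NewickParseError` with the
    parser's position diagnostics on malformed input.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick: {exc}") from None

    children: dict[int, list[int]] = {}
    names: dict[int, str] = {}
    ids: dict[int, int] = {}

    def nid(node: dendropy.Node) -> int:
        key = id(node)
        if key not in ids:
            ids[key] = len(ids)
        return ids[key]

    root = dtree.seed_node
    for node in dtree.preorder_node_iter():
        v = nid(node)
        kids = node.child_nodes()
        children[v] = [nid(c) for c in kids]
        if not kids:
            label = node.taxon.label if node.taxon is not None else node.label
            if label is None:
                raise NewickParseError("leaf without a name in Newick input")
            names[v] = label
        elif node.label:
            names[v] = node.label
    return RootedTree(children, names, nid(root))


def read_leaf_lengths(source: str | io.TextIOBase) -> dict[str, int]:
    """Read a two-column ``leaf<TAB>length`` table into a mapping.

    A header row ``leaf\\tlength`` is recognised and skipped.  Lengths must be
    nonnegative integers; a repeated leaf name is an error here (use the
    paralog reader in :mod:`aglr.preprocess` for multi-copy tables).
    """
    if isinstance(source, str) and "\t" not in source and "\n" not in source:
        with open(source) as fh:
            return read_leaf_lengths(fh)
    if isinstance(source, str):
        source = io.StringIO(source)
    frame = pd.read_csv(source, sep="\t", header=None, comment="#", dtype=str)
    if frame.shape[1] < 2:
        raise ValueError("leaf-length table needs two tab-separated columns")
    frame = frame.iloc[:, :2]
    frame.columns = ["leaf", "length"]
    if frame.iloc[0]["leaf"].strip().lower() == "leaf":
        frame = frame.iloc[1:]
    lengths: dict[str, int] = {}
    for _, row in frame.iterrows():
        name = str(row["leaf"]).strip()
        raw = str(row["length"]).strip()
        try:
            value = int(raw)
        except ValueError:
            raise ValueError(f"non-integer length {raw!r} for leaf {name!r}") from None
        if value < 0:
            raise ValueError(f"negative length {value} for leaf {name!r}")
        if name in lengths:
            raise ValueError(
                f"repeated leaf {name!r}; collapse paralogs first (aglr preprocess)"
            )
        lengths[name] = value
    return lengths


def align_lengths(
    tree: RootedTree, lengths: Mapping[str, int], strict: bool = False
) -> dict[str, int]:
    """Match a length table against a tree's leaves.

    Leaves absent from the table default to 0 ("no value") with a logged
    warning; in ``strict`` mode they are an error.  Table entries that match
    no leaf are always an error.
    """
    leaf_set = set(tree.leaf_names)
    unknown = sorted(set(lengths) - leaf_set)
    if unknown:
        raise ValueError(f"length table rows match no tree leaf: {unknown}")
    out: dict[str, int] = {}
    missing: list[str] = []
    for name in tree.leaf_names:
        if name in lengths:
            value = int(lengths[name])
            if value < 0:
                raise ValueError(f"negative length for leaf {name!r}")
            out[name] = value
        else:
            missing.append(name)
            out[name] = 0
    if missing:
        if strict:
            raise ValueError(f"leaves missing from length table: {missing}")
        log.warning("leaves %s missing from length table; treated as absent (0)", missing)
    return out


def write_labeled_newick(tree: RootedTree, labeling: Mapping[int, int]) -> str:
    """Serialise a fully labeled tree; see :meth:`RootedTree.to_newick`."""
    return tree.to_newick(labels=labeling)
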