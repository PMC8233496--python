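"""Rooted-tree data model, newick I/O, taxon meta-tags and patristic distances.

The :class:`RootedTree` is the universal substrate of the toolkit: a rooted
(binary or multifurcating) phylogeny whose branch lengths are expected
substitutions per site, with an open per-node string annotation map used to
carry node times, confidence intervals and simulation truth.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import dendropy

from .errors import NewickParseError, ConfigurationError

__all__ = [
    "Node",
    "RootedTree",
    "TaxonMeta",
    "read_newick",
    "write_newick",
    "patristic_distances",
    "patristic_table",
    "parse_taxon_meta",
]


class Node:
    """One node of a rooted tree.

    ``length`` is the branch length to the parent (ignored for the root);
    ``name`` is set for tips (and optionally for internal nodes);
    ``annotations`` is a free-form string->string map.
    """

    __slots__ = ("id", "parent", "children", "length", "name", "annotations")

    def __init__(self, id: int, name: Optional[str] = None, length: float = 0.0):
        self.id = id
        self.parent: Optional["Node"] = None
        self.children: list["Node"] = []
        self.length = length
        self.name = name
        self.annotations: dict[str, str] = {}

    @property
    def is_tip(self) -> bool:
        return not self.children

    @property
    def is_root(self) -> bool:
        return self.parent is None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else "node"
        return f"<{kind} {self.id} {self.name or ''}:{self.length:g}>"


class RootedTree:
    """A rooted phylogeny with branch lengths.

    Nodes are stored in a list indexed by ``node.id`` (preorder at
    construction time).  Invariants (checked by :meth:`validate`): exactly one
    root, unique non-empty tip names, finite non-negative branch lengths.
    """

    def __init__(self, root: Node, nodes: Sequence[Node]):
        self.root = root
        self.nodes: list[Node] = list(nodes)

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_root(cls, root: Node) -> "RootedTree":
        """Build the node index from a linked root, assigning preorder ids."""
        nodes: list[Node] = []
        stack = [root]
        while stack:
            nd = stack.pop()
            nd.id = len(nodes)
            nodes.append(nd)
            stack.extend(reversed(nd.children))
        return cls(root, nodes)

    # -- traversal ------------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            nd = stack.pop()
            yield nd
            stack.extend(reversed(nd.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            nd = stack.pop()
            out.append(nd)
            stack.extend(nd.children)
        return iter(reversed(out))

    def tips(self) -> list[Node]:
        return [nd for nd in self.preorder() if nd.is_tip]

    def tip_names(self) -> list[str]:
        return [nd.name for nd in self.tips()]

    @property
    def n_tips(self) -> int:
        return sum(1 for nd in self.nodes if nd.is_tip)

    def tip(self, name: str) -> Node:
        for nd in self.nodes:
            if nd.is_tip and nd.name == name:
                return nd
        raise ConfigurationError(f"no tip named {name!r} in tree")

    def mrca(self, names: Sequence[str]) -> Node:
        """Most recent common ancestor of the named tips."""
        paths = []
        for name in names:
            nd = self.tip(name)
            path = []
            while nd is not None:
                path.append(nd)
                nd = nd.parent
            paths.append(list(reversed(path)))
        anc = self.root
        for level in zip(*paths):
            if all(nd is level[0] for nd in level):
                anc = level[0]
            else:
                break
        return anc

    # -- editing --------------------------------------------------------------

    def copy(self) -> "RootedTree":
        new = [Node(nd.id, nd.name, nd.length) for nd in self.nodes]
        for nd in self.nodes:
            cp = new[nd.id]
            cp.annotations = dict(nd.annotations)
            cp.children = [new[c.id] for c in nd.children]
            for c in cp.children:
                c.parent = cp
        return RootedTree(new[self.root.id], new)

    def suppress_unifurcations(self) -> "RootedTree":
        """Return a copy with single-child chains merged (lengths summed)."""
        t = self.copy()
        changed = True
        while changed:
            changed = False
            for nd in list(t.preorder()):
                if not nd.is_tip and len(nd.children) == 1:
                    child = nd.children[0]
                    if nd.is_root:
                        child.parent = None
                        child.length = 0.0
                        t.root = child
                    else:
                        child.length += nd.length
                        child.parent = nd.parent
                        i = nd.parent.children.index(nd)
                        nd.parent.children[i] = child
                    changed = True
        return RootedTree.from_root(t.root)

    # -- validation -----------------------------------------------------------

    def validate(self) -> None:
        seen: set[str] = set()
        for nd in self.preorder():
            if nd.is_tip:
                if not nd.name:
                    raise NewickParseError(f"tip node {nd.id} has no name")
                if nd.name in seen:
                    raise NewickParseError(f"duplicate tip name {nd.name!r}")
                seen.add(nd.name)
            if not nd.is_root:
                if not (nd.length == nd.length and abs(nd.length) != float("inf")):
                    raise NewickParseError(
                        f"non-finite branch length on node {nd.name or nd.id}"
                    )
                if nd.length < 0:
                    raise NewickParseError(
                        f"negative branch length {nd.length} on node "
                        f"{nd.name or nd.id}"
                    )
        n_roots = sum(1 for nd in self.nodes if nd.is_root)
        if n_roots != 1:
            raise NewickParseError(f"tree has {n_roots} roots, expected 1")


# -- newick I/O ----------------------------------------------------------------


def read_newick(text: str) -> RootedTree:
    """Parse a newick string into a :class:`RootedTree`.

    Branch lengths default to 0; quoted and internal-node labels are
    supported.  Raises :class:`NewickParseError` on malformed input,
    duplicate tip names or negative branch lengths.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted error classes
        raise NewickParseError(f"newick parse failed: {exc}") from exc

    def convert(dnode) -> Node:
        if dnode.taxon is not None:
            name = dnode.taxon.label
        else:
            name = dnode.label
        nd = Node(0, name=name, length=dnode.edge.length or 0.0)
        for dchild in dnode.child_nodes():
            child = convert(dchild)
            child.parent = nd
            nd.children.append(child)
        return nd

    tree = RootedTree.from_root(convert(dtree.seed_node))
    tree.validate()
    return tree


_NEEDS_QUOTE = re.compile(r"[\s()\[\]{}:;,'\"]")


def _quote(label: str) -> str:
    if _NEEDS_QUOTE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: RootedTree, annotations: Sequence[str] = ()) -> str:
    """Serialize to newick.

    ``annotations`` names the node-annotation keys to embed; when non-empty
    they are written as a square-bracket comment after the node label,
    ``[&time=...,ci_lo=...,ci_hi=...]``, a dialect accepted by common
    viewers.  With an empty set the output is plain newick.
    """
    keys = list(annotations)

    def comment(nd: Node) -> str:
        if not keys:
            return ""
        items = [(k, nd.annotations[k]) for k in keys if k in nd.annotations]
        if not items:
            return ""
        return "[&" + ",".join(f"{k}={v}" for k, v in items) + "]"

    buf = io.StringIO()

    def write(nd: Node) -> None:
        if nd.children:
            buf.write("(")
            for i, c in enumerate(nd.children):
                if i:
                    buf.write(",")
                write(c)
            buf.write(")")
            if nd.name:
                buf.write(_quote(nd.name))
        else:
            buf.write(_quote(nd.name or ""))
        buf.write(comment(nd))
        if not nd.is_root:
            buf.write(f":{nd.length:.12g}")

    write(tree.root)
    buf.write(";")
    return buf.getvalue()


# -- patristic distances -------------------------------------------------------


def patristic_distances(tree: RootedTree) -> tuple[list[str], "np.ndarray"]:
    """Pairwise tip-to-tip path-length matrix.

    Returns ``(tip_names, matrix)`` with zero diagonal; entry (i, j) is the
    sum of branch lengths on the path between tips i and j.
    """
    import numpy as np

    tips = tree.tips()
    names = [t.name for t in tips]
    index = {t.id: i for i, t in enumerate(tips)}
    n = len(tips)

    depth = {tree.root.id: 0.0}
    for nd in tree.preorder():
        if not nd.is_root:
            depth[nd.id] = depth[nd.parent.id] + nd.length

    # tips below each node, accumulated postorder; pairs split across
    # children of a node have that node as their MRCA
    dist = np.zeros((n, n))
    below: dict[int, list[int]] = {}
    for nd in tree.postorder():
        if nd.is_tip:
            below[nd.id] = [nd.id]
            continue
        groups = [below[c.id] for c in nd.children]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a in groups[gi]:
                    for b in groups[gj]:
                        d = depth[a] + depth[b] - 2.0 * depth[nd.id]
                        ia, ib = index[a], index[b]
                        dist[ia, ib] = dist[ib, ia] = d
        below[nd.id] = [t for g in groups for t in g]
    return names, dist


def patristic_table(tree: RootedTree) -> str:
    """Patristic distances as TSV: ``taxon_i<TAB>taxon_j<TAB>distance``."""
    names, dist = patristic_distances(tree)
    lines = ["taxon_i\ttaxon_j\tdistance"]
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            lines.append(f"{names[i]}\t{names[j]}\t{dist[i, j]:.10g}")
    return "\n".join(lines) + "\n"


# -- taxon meta-tags -----------------------------------------------------------

_META_FIELDS = (
    "name",
    "group",
    "continent",
    "country",
    "city",
    "date",
    "year",
    "month",
    "day",
    "time",
)


@dataclass
class TaxonMeta:
    """Spatiotemporal metadata extracted from a taxon name.

    ``year``/``month``/``day``, when all present, form a valid calendar
    date; malformed components are left empty and recorded in ``warnings``.
    """

    name: str = ""
    group: str = ""
    continent: str = ""
    country: str = ""
    city: str = ""
    year: Optional[int] = None
    month: Optional[int] = None
    day: Optional[int] = None
    time: str = ""
    warnings: list[str] = field(default_factory=list)


_DAYS_IN_MONTH = (31, 29, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)


def _valid_date(y: int, m: Optional[int], d: Optional[int]) -> bool:
    if m is not None and not (1 <= m <= 12):
        return False
    if d is not None:
        if m is None:
            return False
        if not (1 <= d <= _DAYS_IN_MONTH[m - 1]):
            return False
        if m == 2 and d == 29:
            leap = y % 4 == 0 and (y % 100 != 0 or y % 400 == 0)
            if not leap:
                return False
    return True


def parse_taxon_meta(name: str, pattern: str, delimiter: str = "|") -> TaxonMeta:
    """Extract tagged fields from a taxon name.

    ``pattern`` is a delimiter-separated list of reserved field names, e.g.
    ``"name|country|date"``; the taxon name is split on the same delimiter
    and fields are assigned positionally.  A ``date`` field accepts ISO
    YYYY[-MM[-DD]].  Missing or malformed components never raise — they are
    left empty with a warning recorded on the returned :class:`TaxonMeta`.
    """
    fields = [f.strip().lower() for f in pattern.split(delimiter)]
    for f in fields:
        if f not in _META_FIELDS:
            raise ConfigurationError(
                f"unknown meta field {f!r}; expected one of {_META_FIELDS}"
            )
    parts = name.split(delimiter)
    meta = TaxonMeta()
    if len(parts) < len(fields):
        meta.warnings.append(
            f"taxon {name!r}: {len(parts)} field(s) found, pattern expects "
            f"{len(fields)}; missing fields left empty"
        )
    for f, value in zip(fields, parts):
        value = value.strip()
        if f == "date":
            _assign_date(meta, value, name)
        elif f in ("year", "month", "day"):
            try:
                setattr(meta, f, int(value))
            except ValueError:
                meta.warnings.append(f"taxon {name!r}: bad {f} {value!r}")
        else:
            setattr(meta, f, value)
    if meta.year is not None and not _valid_date(meta.year, meta.month, meta.day):
        meta.warnings.append(
            f"taxon {name!r}: invalid calendar date "
            f"{meta.year}-{meta.month}-{meta.day}; month/day cleared"
        )
        meta.month = meta.day = None
    return meta


def _assign_date(meta: TaxonMeta, value: str, name: str) -> None:
    if not value:
        meta.warnings.append(f"taxon {name!r}: empty date field")
        return
    bits = value.split("-")
    try:
        meta.year = int(bits[0])
        if len(bits) > 1:
            meta.month = int(bits[1])
        if len(bits) > 2:
            meta.day = int(bits[2])
    except ValueError:
        meta.warnings.append(f"taxon {name!r}: unparseable date {value!r}")
        meta.year = meta.month = meta.day = None
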