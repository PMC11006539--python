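"""Tree plumbing: newick I/O, surgery primitives, Jukes-Cantor distances, neighbor joining.

Trees are stored rooted (a root node with children) but most pipeline
operations treat them as unrooted; the root is just an anchor.  Tip labels
are sample identifiers with an optional copy suffix (``Sample_07@2``); the
taxon of a tip is the label before ``@``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Node",
    "GeneTree",
    "DistanceMatrix",
    "NewickError",
    "UndefinedDistanceError",
    "taxon_of",
    "parse_newick",
    "jc_distance",
    "jc_distance_matrix",
    "neighbor_joining",
]


class NewickError(ValueError):
    """Malformed newick input; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class UndefinedDistanceError(ValueError):
    """Jukes-Cantor distance undefined (saturation or no comparable sites)."""


def taxon_of(label: str) -> str:
    """Taxon (sample id) of a tip label: the part before the copy suffix '@'."""
    return label.split("@", 1)[0]


class Node:
    """One tree node; ``length`` is the branch above it (0.0 at the root)."""

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: str | None = None, length: float = 0.0):
        self.label = label
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def detach_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    def preorder(self):
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self):
        out = list(self.preorder())
        return reversed(out)

    def copy(self) -> "Node":
        clone = Node(self.label, self.length)
        for child in self.children:
            clone.add_child(child.copy())
        return clone

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, {self.length})"


@dataclass
class GeneTree:
    """A gene tree with branch lengths in substitutions per site."""

    root: Node

    # -- queries ---------------------------------------------------------

    def tips(self) -> list[Node]:
        return [n for n in self.root.preorder() if n.is_tip]

    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips()]

    def taxa(self) -> set[str]:
        return {taxon_of(t.label) for t in self.tips()}

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def total_length(self) -> float:
        return float(sum(n.length for n in self.root.preorder() if n.parent is not None))

    def internal_nodes(self) -> list[Node]:
        """Non-root nodes with children; their parent edges are the internal edges."""
        return [n for n in self.root.preorder() if n.children and n.parent is not None]

    def copy(self) -> "GeneTree":
        return GeneTree(self.root.copy())

    # -- surgery ---------------------------------------------------------

    def suppress_degree_two(self) -> None:
        """Collapse unifurcations (merged edge lengths sum) and drop empty internals.

        A root left with a single child is replaced by that child; the
        child's now-dangling root edge is discarded (an unrooted tree has
        no root edge).
        """
        changed = True
        while changed:
            changed = False
            for node in list(self.root.postorder()):
                if node.parent is None:
                    continue
                if not node.children and node.label is None:
                    node.parent.children.remove(node)
                    changed = True
                elif len(node.children) == 1:
                    child = node.children[0]
                    child.length += node.length
                    parent = node.parent
                    idx = parent.children.index(node)
                    parent.children[idx] = child
                    child.parent = parent
                    changed = True
            while len(self.root.children) == 1 and self.root.children[0].children:
                new_root = self.root.children[0]
                new_root.parent = None
                new_root.length = 0.0
                self.root = new_root
                changed = True

    def remove_tip_nodes(self, tips_to_remove) -> None:
        """Detach the given tip nodes, then clean up the topology."""
        doomed = set(id(t) for t in tips_to_remove)
        for node in list(self.root.preorder()):
            if node.is_tip and id(node) in doomed and node.parent is not None:
                node.parent.children.remove(node)
                node.parent = None
        self.suppress_degree_two()

    def remove_tips_by_label(self, labels) -> None:
        labels = set(labels)
        self.remove_tip_nodes([t for t in self.tips() if t.label in labels])

    # -- serialization ---------------------------------------------------

    def write(self) -> str:
        """Newick string; labels unquoted, no support values, lengths %.12g."""

        def fmt(node: Node) -> str:
            if node.is_tip:
                core = node.label or ""
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.parent is None:
                return core
            return f"{core}:{node.length:.12g}"

        return fmt(self.root) + ";"

    def __str__(self):
        return self.write()


_LABEL_END = set(":,();")


def parse_newick(text: str) -> GeneTree:
    """Parse a single newick expression into a :class:`GeneTree`.

    Absent branch lengths default to 0.0.  Internal labels / support values
    after ')' are accepted and discarded.  Raises :class:`NewickError` with
    the offending position on malformed input.
    """
    s = text.strip()
    if not s:
        raise NewickError("empty newick input", 0)
    pos = 0

    def read_label() -> str:
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] not in _LABEL_END:
            pos += 1
        return s[start:pos].strip()

    def read_length() -> float:
        nonlocal pos
        start = pos
        while pos < len(s) and (s[pos] in "+-.eE" or s[pos].isdigit()):
            pos += 1
        token = s[start:pos]
        try:
            return float(token)
        except ValueError:
            raise NewickError(f"invalid branch length {token!r}", start) from None

    def parse_clade() -> Node:
        nonlocal pos
        node = Node()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.add_child(parse_clade())
                if pos >= len(s):
                    raise NewickError("unbalanced parentheses", pos)
                if s[pos] == ",":
                    pos += 1
                elif s[pos] == ")":
                    pos += 1
                    break
                else:
                    raise NewickError(f"unexpected character {s[pos]!r}", pos)
            read_label()  # internal label or support value: discarded
        else:
            label = read_label()
            if not label:
                raise NewickError("expected a tip label", pos)
            node.label = label
        if pos < len(s) and s[pos] == ":":
            pos += 1
            node.length = read_length()
        return node

    root = parse_clade()
    if pos >= len(s) or s[pos] != ";":
        raise NewickError("expected ';' to terminate the tree", pos)
    if s[pos + 1 :].strip():
        raise NewickError("trailing characters after ';'", pos + 1)
    if sum(1 for n in root.preorder() if n.is_tip) < 2:
        raise NewickError("tree must have at least 2 tips", 0)
    return GeneTree(root)


def read_newick_file(path) -> list[GeneTree]:
    """One tree per non-empty line."""
    trees = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(parse_newick(line))
    return trees


def write_newick_file(trees, path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.write() + "\n")


# ---------------------------------------------------------------------------
# Jukes-Cantor distances
# ---------------------------------------------------------------------------

_VALID = np.frombuffer(b"ACGT", dtype="S1")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype="S1")


def jc_distance(a: str, b: str) -> float:
    """Jukes-Cantor distance -(3/4) ln(1 - 4p/3) over comparable sites.

    Sites where either sequence has a gap, N or other ambiguity are
    excluded.  Raises :class:`UndefinedDistanceError` when no sites are
    comparable or the mismatch proportion is >= 0.75 (saturation).
    """
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    ea, eb = _encode(a), _encode(b)
    ok = np.isin(ea, _VALID) & np.isin(eb, _VALID)
    n = int(ok.sum())
    if n == 0:
        raise UndefinedDistanceError("no comparable sites")
    p = float((ea[ok] != eb[ok]).sum()) / n
    if p >= 0.75:
        raise UndefinedDistanceError(f"mismatch proportion {p:.3f} >= 0.75 (saturated)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def jc_distance_matrix(labels, seqs, saturation_cap: float | None = None) -> "DistanceMatrix":
    """Pairwise JC distances for equal-length sequences.

    With ``saturation_cap`` set, saturated / incomparable pairs get that cap
    instead of raising; the pipeline uses this so one bad pair cannot abort
    a whole cluster.
    """
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                dij = jc_distance(seqs[i], seqs[j])
            except UndefinedDistanceError:
                if saturation_cap is None:
                    raise
                dij = saturation_cap
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(list(labels), d)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (self.d < -1e-12).any():
            raise ValueError("distances must be non-negative")


def neighbor_joining(dm: DistanceMatrix) -> GeneTree:
    """Saitou-Nei neighbor joining; negative branch lengths clamped to 0.

    Returns an unrooted tree (root is the final trifurcation, or the single
    edge midpoint for two labels).
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least 2 labels")
    nodes = [Node(lbl) for lbl in dm.labels]
    if n == 2:
        root = Node()
        a, b = nodes
        a.length = b.length = max(dm.d[0, 1] / 2.0, 0.0)
        root.add_child(a)
        root.add_child(b)
        return GeneTree(root)

    d = dm.d.copy()
    active = list(range(n))
    node_for = {i: nodes[i] for i in range(n)}
    next_id = n

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_, j_ = np.unravel_index(np.argmin(q), q.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        gi, gj = active[i_], active[j_]
        dij = sub[i_, j_]
        li = 0.5 * dij + (r[i_] - r[j_]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = Node()
        node_for[gi].length = li
        node_for[gj].length = lj
        new.add_child(node_for[gi])
        new.add_child(node_for[gj])
        # grow d with the new node's row
        new_row = np.zeros(d.shape[0] + 1)
        for k in active:
            if k in (gi, gj):
                continue
            new_row[k] = max(0.5 * (d[gi, k] + d[gj, k] - dij), 0.0)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[next_id, : next_id] = new_row[:next_id]
        d[: next_id, next_id] = new_row[:next_id]
        node_for[next_id] = new
        active = [k for k in active if k not in (gi, gj)] + [next_id]
        next_id += 1

    root = Node()
    a, b, c = active
    la = max(0.5 * (d[a, b] + d[a, c] - d[b, c]), 0.0)
    lb = max(0.5 * (d[a, b] + d[b, c] - d[a, c]), 0.0)
    lc = max(0.5 * (d[a, c] + d[b, c] - d[a, b]), 0.0)
    for g, ln in zip((a, b, c), (la, lb, lc)):
        node_for[g].length = ln
        root.add_child(node_for[g])
    return GeneTree(root)
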