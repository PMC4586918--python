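"""SWC neuron-morphology data model.

An SWC file stores a neuron reconstruction as a rooted forest of spheres:
one node per line with seven whitespace-separated columns
``id type x y z radius parent`` (parent ``-1`` marks a root).  In memory
each node carries, besides its geometry, three structural links --
parent, first child and next sibling -- so every neighbourhood query
(parent, children, siblings) is O(1) without scanning the whole tree.
The price of the redundancy is a set of consistency rules that every
public operation must preserve:

* parent links are acyclic (following the parent chain from any node
  terminates at a root);
* if a node has a first child, that child's parent link points back to
  the node;
* siblings share a parent: ``P(S(n)) == P(n)``;
* sibling chains terminate and never visit a node twice, and every
  child is reachable from its parent through the first-child /
  next-sibling chain.

``validate_tree`` audits exactly these rules and is the gatekeeper used
by the file writer and by the test-suite properties.

Conventions (the SWC dialect accepted here): ``#`` begins a comment
line; ids are positive integers, not required to be contiguous; the
type column is preserved verbatim and never interpreted; sibling order
on read equals the file order of the children, which makes
read/write round-trips deterministic.  Coordinates are continuous
positions in the image coordinate frame with the centre of voxel
(0, 0, 0) at the origin and 0-based voxel indexing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "SwcError",
    "SwcParseError",
    "UnknownNodeError",
    "InvalidTreeError",
    "SwcNode",
    "SwcTree",
    "ValidationReport",
    "read_swc",
    "write_swc",
    "validate_tree",
    "upstream_path",
    "children_of",
]


class SwcError(Exception):
    """Base class for all errors raised by this package."""


class SwcParseError(SwcError):
    """Malformed SWC input (names the offending line where possible)."""


class UnknownNodeError(SwcError):
    """A node id was referenced that does not exist in the tree."""


class InvalidTreeError(SwcError):
    """An operation required a structurally valid tree and got none."""


class SwcNode:
    """A single reconstruction node: a sphere plus three structural links.

    The link fields hold node *ids* (or ``None`` for the empty node, the
    distinguished sentinel that roots hang from).  Geometry is a centre
    in image coordinates and a strictly positive radius in the same
    units; the SWC type code is carried through untouched.
    """

    __slots__ = ("id", "type_code", "center", "radius",
                 "parent", "first_child", "next_sibling")

    def __init__(self, node_id: int, type_code: int, center, radius: float,
                 parent: int | None = None, first_child: int | None = None,
                 next_sibling: int | None = None):
        node_id = int(node_id)
        if node_id <= 0:
            raise SwcError(f"node id must be a positive integer, got {node_id}")
        center = np.asarray(center, dtype=float)
        if center.shape != (3,) or not np.all(np.isfinite(center)):
            raise SwcError(f"node {node_id}: centre must be a finite 3-vector")
        radius = float(radius)
        if not (radius > 0 and math.isfinite(radius)):
            raise SwcError(f"node {node_id}: radius must be positive and finite")
        self.id = node_id
        self.type_code = int(type_code)
        self.center = center
        self.radius = radius
        self.parent = parent
        self.first_child = first_child
        self.next_sibling = next_sibling

    def copy(self) -> "SwcNode":
        return SwcNode(self.id, self.type_code, self.center.copy(), self.radius,
                       self.parent, self.first_child, self.next_sibling)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"SwcNode({self.id}, t={self.type_code}, "
                f"c={tuple(round(float(v), 3) for v in self.center)}, r={self.radius:g}, "
                f"P={self.parent}, C={self.first_child}, S={self.next_sibling})")


class SwcTree:
    """A forest of :class:`SwcNode` keyed by id.

    Iteration order is insertion order, which for trees built by
    :func:`read_swc` equals file order; the writer relies on this to
    produce deterministic round trips.  The ``journal`` attribute is
    attached lazily by the operation layer and records every reversible
    change made through it.
    """

    def __init__(self) -> None:
        self._nodes: dict[int, SwcNode] = {}
        self.journal = None  # attached by swcedit.ops on first use

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, node_id: int) -> bool:
        return node_id in self._nodes

    def __getitem__(self, node_id: int) -> SwcNode:
        try:
            return self._nodes[node_id]
        except KeyError:
            raise UnknownNodeError(f"no node with id {node_id}") from None

    def __iter__(self) -> Iterator[SwcNode]:
        return iter(self._nodes.values())

    def ids(self) -> list[int]:
        return list(self._nodes.keys())

    # -- construction --------------------------------------------------------

    def add(self, node: SwcNode) -> SwcNode:
        if node.id in self._nodes:
            raise SwcError(f"duplicate node id {node.id}")
        self._nodes[node.id] = node
        return node

    def _pop(self, node_id: int) -> SwcNode:
        """Remove a node from the container.

        Internal: public deletion goes through the journalled edit
        operations, which detach the node first.
        """
        try:
            return self._nodes.pop(node_id)
        except KeyError:
            raise UnknownNodeError(f"no node with id {node_id}") from None

    def next_id(self) -> int:
        return max(self._nodes, default=0) + 1

    # -- structural queries --------------------------------------------------

    def roots(self) -> list[int]:
        return [n.id for n in self._nodes.values() if n.parent is None]

    def children_of(self, node_id: int) -> list[int]:
        """Children of a node, first child then along the sibling chain."""
        node = self[node_id]
        out: list[int] = []
        seen: set[int] = set()
        cur = node.first_child
        while cur is not None:
            if cur in seen or cur not in self._nodes:
                raise InvalidTreeError(
                    f"corrupt sibling chain under node {node_id}")
            seen.add(cur)
            out.append(cur)
            cur = self._nodes[cur].next_sibling
        return out

    def parent_of(self, node_id: int) -> int | None:
        return self[node_id].parent

    def degree(self, node_id: int) -> int:
        """Total degree: parent edge (if any) plus number of children."""
        node = self[node_id]
        return (node.parent is not None) + len(self.children_of(node_id))

    def upstream_path(self, ni: int, nj: int) -> list[int]:
        """Ancestor chain from ``ni`` up to ``nj`` inclusive, or ``[]``.

        Each element's successor is its parent; empty when ``nj`` is not
        an ancestor of ``ni`` (a node counts as its own ancestor).
        """
        self[nj]
        path = [ni]
        seen = {ni}
        cur = self[ni]
        while cur.id != nj:
            if cur.parent is None:
                return []
            if cur.parent in seen or cur.parent not in self._nodes:
                raise InvalidTreeError("cycle or dangling link in parent chain")
            seen.add(cur.parent)
            path.append(cur.parent)
            cur = self._nodes[cur.parent]
        return path

    def root_of(self, node_id: int) -> int:
        """The root reached by following parent links from ``node_id``."""
        seen = set()
        cur = self[node_id]
        while cur.parent is not None:
            if cur.id in seen:
                raise InvalidTreeError("cycle in parent chain")
            seen.add(cur.id)
            cur = self[cur.parent]
        return cur.id

    def component_of(self, node_id: int) -> set[int]:
        """Ids of every node in the connected component of ``node_id``."""
        root = self.root_of(node_id)
        comp = set()
        stack = [root]
        while stack:
            nid = stack.pop()
            comp.add(nid)
            stack.extend(self.children_of(nid))
        return comp

    def components(self) -> list[set[int]]:
        """All connected components, ordered by their smallest member id."""
        comps = []
        seen: set[int] = set()
        for nid in self._nodes:
            if nid in seen:
                continue
            comp = self.component_of(nid)
            seen |= comp
            comps.append(comp)
        return sorted(comps, key=min)

    # -- comparison / copy ---------------------------------------------------

    def copy(self) -> "SwcTree":
        out = SwcTree()
        for node in self:
            out._nodes[node.id] = node.copy()
        return out

    def structurally_equal(self, other: "SwcTree", *, atol: float = 0.0) -> bool:
        """Node-for-node equality of ids, links, type codes and geometry.

        ``atol=0`` demands exact geometry (the undo contract);
        a positive ``atol`` tolerates printed-precision drift
        (the file round-trip contract).
        """
        if set(self._nodes) != set(other._nodes):
            return False
        for nid, a in self._nodes.items():
            b = other._nodes[nid]
            if (a.parent, a.first_child, a.next_sibling, a.type_code) != \
               (b.parent, b.first_child, b.next_sibling, b.type_code):
                return False
            if atol == 0.0:
                if not (np.array_equal(a.center, b.center) and a.radius == b.radius):
                    return False
            else:
                if not (np.allclose(a.center, b.center, atol=atol, rtol=1e-6)
                        and math.isclose(a.radius, b.radius, rel_tol=1e-5, abs_tol=atol)):
                    return False
        return True


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Outcome of a structural audit: a list of (rule, offending ids)."""

    violations: list[tuple[str, tuple[int, ...]]] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not self.violations

    def summary(self) -> str:
        if self.is_valid:
            return "valid"
        return "; ".join(f"{rule}: nodes {sorted(set(ids))}"
                         for rule, ids in self.violations)


def validate_tree(tree: SwcTree) -> ValidationReport:
    """Audit every redundancy and acyclicity rule of the node model.

    Checks, in order: dangling link targets, parent-link acyclicity,
    parent/first-child agreement (``P(C(n)) == n``), sibling parent
    agreement (``P(S(n)) == P(n)``), sibling-chain termination and
    uniqueness, and reachability of every child from its parent through
    the first-child/next-sibling chain.  Always returns a report and
    never raises.
    """
    report = ValidationReport()
    nodes = tree._nodes

    def bad(rule: str, *ids: int) -> None:
        report.violations.append((rule, tuple(ids)))

    for n in nodes.values():
        for link in (n.parent, n.first_child, n.next_sibling):
            if link is not None and link not in nodes:
                bad("dangling_link", n.id)

    # parent acyclicity, memoising chains known to reach a root
    safe: set[int] = set()
    for n in nodes.values():
        chain = []
        cur = n
        while True:
            if cur.id in safe:
                break
            if cur.id in chain:
                bad("parent_cycle", cur.id)
                break
            chain.append(cur.id)
            if cur.parent is None or cur.parent not in nodes:
                break
            cur = nodes[cur.parent]
        safe.update(chain)

    for n in nodes.values():
        c = n.first_child
        if c is not None and c in nodes and nodes[c].parent != n.id:
            bad("child_parent_mismatch", n.id, c)
        s = n.next_sibling
        if s is not None and s in nodes and nodes[s].parent != n.parent:
            bad("sibling_parent_mismatch", n.id, s)

    # sibling-chain termination, uniqueness and coverage
    chain_membership: dict[int, int] = {}
    for n in nodes.values():
        seen_chain: set[int] = set()
        cur = n.first_child
        steps = 0
        while cur is not None and cur in nodes:
            if cur in seen_chain:
                bad("sibling_cycle", n.id, cur)
                break
            seen_chain.add(cur)
            if cur in chain_membership and chain_membership[cur] != n.id:
                bad("sibling_duplicate", cur)
            chain_membership[cur] = n.id
            cur = nodes[cur].next_sibling
            steps += 1
            if steps > len(nodes):  # pragma: no cover - guarded by seen_chain
                bad("sibling_cycle", n.id)
                break
        expected = {m.id for m in nodes.values() if m.parent == n.id}
        if expected != seen_chain:
            missing = expected - seen_chain
            if missing:
                bad("unreachable_from_parent", n.id, *sorted(missing))

    return report


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_swc(path) -> SwcTree:
    """Parse an SWC file into a tree.

    One node per non-comment line; the redundant first-child /
    next-sibling links are reconstructed from the parent column with
    sibling order equal to file order.  Raises :class:`SwcParseError`
    (naming the line) on malformed lines, duplicate ids, absent parents
    or cycles in the parent column.
    """
    tree = SwcTree()
    parent_col: dict[int, int] = {}
    order: list[int] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 7:
                raise SwcParseError(
                    f"{path}:{lineno}: expected >=7 fields, got {len(parts)}")
            try:
                nid = int(parts[0])
                type_code = int(parts[1])
                x, y, z, r = (float(v) for v in parts[2:6])
                pid = int(parts[6])
            except ValueError as exc:
                raise SwcParseError(f"{path}:{lineno}: {exc}") from None
            if nid in parent_col:
                raise SwcParseError(f"{path}:{lineno}: duplicate id {nid}")
            try:
                tree.add(SwcNode(nid, type_code, (x, y, z), r))
            except SwcError as exc:
                raise SwcParseError(f"{path}:{lineno}: {exc}") from None
            parent_col[nid] = pid
            order.append(nid)

    children: dict[int, list[int]] = {}
    for nid in order:
        pid = parent_col[nid]
        if pid == -1:
            continue
        if pid not in tree:
            raise SwcParseError(
                f"{path}: node {nid} references absent parent {pid}")
        tree[nid].parent = pid
        children.setdefault(pid, []).append(nid)

    for pid, kids in children.items():
        tree[pid].first_child = kids[0]
        for a, b in zip(kids, kids[1:]):
            tree[a].next_sibling = b

    report = validate_tree(tree)
    if not report.is_valid:
        raise SwcParseError(f"{path}: invalid structure ({report.summary()})")
    return tree


def write_swc(tree: SwcTree, path) -> None:
    """Write a tree as standard 7-column SWC text.

    Nodes are emitted in depth-first preorder per root (parents always
    before children, children in sibling-chain order), so reading the
    file back reproduces the tree link-for-link.  Refuses to write a
    tree that fails :func:`validate_tree`.
    """
    report = validate_tree(tree)
    if not report.is_valid:
        raise InvalidTreeError(f"refusing to write invalid tree: {report.summary()}")
    lines = []
    for root in tree.roots():
        stack = [root]
        while stack:
            nid = stack.pop()
            n = tree[nid]
            pid = -1 if n.parent is None else n.parent
            x, y, z = (f"{float(v):.9g}" for v in n.center)
            lines.append(f"{n.id} {n.type_code} {x} {y} {z} {n.radius:.6g} {pid}")
            stack.extend(reversed(tree.children_of(nid)))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# functional wrappers (module-level operation surface)
# ---------------------------------------------------------------------------

def upstream_path(tree: SwcTree, ni: int, nj: int) -> list[int]:
    """Ancestor chain from ``ni`` to ``nj``; see :meth:`SwcTree.upstream_path`."""
    return tree.upstream_path(ni, nj)


def children_of(tree: SwcTree, n: int) -> list[int]:
    """Ordered children of ``n``; see :meth:`SwcTree.children_of`."""
    return tree.children_of(n)
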