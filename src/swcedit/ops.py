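"""Three-level operation algebra over SWC trees, with a reversible journal.

Structural edits are layered so that validity and undo both come for
free at the top:

* **Level 1** -- the elementary link writes ``f_p`` (parent), ``f_c``
  (first child) and ``f_s`` (next sibling).  Each overwrites exactly one
  link field of one node and returns a record of the change.  Validity
  is *not* guaranteed at this level.
* **Level 2** -- the simple valid compositions: ``detach`` (set parent
  to the empty node, repairing the old parent's child/sibling chain),
  ``set_parent`` (detach, then insert as the target's first child) and
  ``set_sibling`` (detach the other node, then insert it as the next
  sibling).  Each leaves the tree valid.
* **Level 3** -- arbitrary compositions of level-2 operations (see
  :mod:`swcedit.edits`).

Every change made through this layer appends an elementary record to an
open journal entry; undo replays the inverses of an entry's records in
reverse order, which restores the prior tree exactly, and redo replays
them forward.  One public operation equals one journal entry, so one
undo reverts one user action.

Besides the three link kinds the journal also records geometry changes
and node creation/deletion: reversing a delete must resurrect the node
and reversing a geometric edit must restore the old centre and radius,
neither of which a link record can express.
"""

from __future__ import annotations

from contextlib import contextmanager
from dataclasses import dataclass, field, replace
from typing import Iterator, Union

import numpy as np

from .model import InvalidTreeError, SwcError, SwcNode, SwcTree, UnknownNodeError

__all__ = [
    "ElementaryOpRecord",
    "GeometryOpRecord",
    "CreateNodeRecord",
    "DeleteNodeRecord",
    "CompositeEntry",
    "Journal",
    "LoopError",
    "journal_of",
    "op_transaction",
    "link_parent",
    "link_child",
    "link_sibling",
    "detach",
    "set_parent",
    "set_sibling",
    "is_ancestor",
    "undo",
    "redo",
]


class LoopError(SwcError):
    """The requested structural change would create a parent-link cycle."""


_LINK_FIELD = {
    "set_parent_link": "parent",
    "set_child_link": "first_child",
    "set_sibling_link": "next_sibling",
}


@dataclass(frozen=True)
class ElementaryOpRecord:
    """One level-1 link write together with the value it overwrote."""

    kind: str                   # set_parent_link | set_child_link | set_sibling_link
    node: int
    old_target: int | None
    new_target: int | None

    def apply(self, tree: SwcTree) -> None:
        setattr(tree[self.node], _LINK_FIELD[self.kind], self.new_target)

    def inverted(self) -> "ElementaryOpRecord":
        return replace(self, old_target=self.new_target, new_target=self.old_target)


@dataclass(frozen=True)
class GeometryOpRecord:
    """A reversible change of a node's centre and/or radius."""

    node: int
    old_center: tuple[float, float, float]
    old_radius: float
    new_center: tuple[float, float, float]
    new_radius: float

    def apply(self, tree: SwcTree) -> None:
        n = tree[self.node]
        n.center = np.asarray(self.new_center, dtype=float)
        n.radius = float(self.new_radius)

    def inverted(self) -> "GeometryOpRecord":
        return GeometryOpRecord(self.node, self.new_center, self.new_radius,
                                self.old_center, self.old_radius)


@dataclass(frozen=True)
class CreateNodeRecord:
    """Creation of a fresh, link-less node (inverse: deletion)."""

    node: int
    type_code: int
    center: tuple[float, float, float]
    radius: float

    def apply(self, tree: SwcTree) -> None:
        tree.add(SwcNode(self.node, self.type_code, self.center, self.radius))

    def inverted(self) -> "DeleteNodeRecord":
        return DeleteNodeRecord(self.node, self.type_code, self.center, self.radius)


@dataclass(frozen=True)
class DeleteNodeRecord:
    """Removal of a fully detached node (inverse: re-creation)."""

    node: int
    type_code: int
    center: tuple[float, float, float]
    radius: float

    def apply(self, tree: SwcTree) -> None:
        n = tree[self.node]
        if not (n.parent is None and n.first_child is None and n.next_sibling is None):
            raise InvalidTreeError(
                f"node {self.node} must be fully detached before removal")
        tree._pop(self.node)

    def inverted(self) -> CreateNodeRecord:
        return CreateNodeRecord(self.node, self.type_code, self.center, self.radius)


OpRecord = Union[ElementaryOpRecord, GeometryOpRecord,
                 CreateNodeRecord, DeleteNodeRecord]


@dataclass
class CompositeEntry:
    """One journalled user action: an ordered record list plus a label."""

    label: str
    records: list[OpRecord] = field(default_factory=list)


class Journal:
    """Reversible history of committed composite entries.

    ``undo`` pops the last committed entry, applies the inverses of its
    records in reverse order and pushes the entry onto the redo stack;
    ``redo`` replays forward.  Committing any new entry clears the redo
    stack.  Depth is unbounded.
    """

    def __init__(self) -> None:
        self.committed: list[CompositeEntry] = []
        self.redo_stack: list[CompositeEntry] = []
        self._open: CompositeEntry | None = None
        self._depth = 0

    def record(self, rec: OpRecord) -> None:
        if self._open is None:
            raise SwcError("no open transaction to record into")
        self._open.records.append(rec)

    @property
    def in_transaction(self) -> bool:
        return self._depth > 0

    def can_undo(self) -> bool:
        return bool(self.committed)

    def can_redo(self) -> bool:
        return bool(self.redo_stack)

    def undo(self, tree: SwcTree) -> bool:
        """Revert the last committed entry; ``False`` signals empty history."""
        if self.in_transaction:
            raise SwcError("cannot undo while an operation is in progress")
        if not self.committed:
            return False
        entry = self.committed.pop()
        for rec in reversed(entry.records):
            rec.inverted().apply(tree)
        self.redo_stack.append(entry)
        return True

    def redo(self, tree: SwcTree) -> bool:
        """Re-apply the last undone entry; ``False`` signals nothing to redo."""
        if self.in_transaction:
            raise SwcError("cannot redo while an operation is in progress")
        if not self.redo_stack:
            return False
        entry = self.redo_stack.pop()
        for rec in entry.records:
            rec.apply(tree)
        self.committed.append(entry)
        return True


def journal_of(tree: SwcTree, journal: Journal | None = None) -> Journal:
    """The journal to use for a tree: an explicit one, or the tree's own."""
    if journal is not None:
        return journal
    if tree.journal is None:
        tree.journal = Journal()
    return tree.journal


@contextmanager
def op_transaction(tree: SwcTree, label: str,
                   journal: Journal | None = None) -> Iterator[CompositeEntry]:
    """Group every record made inside the block into one journal entry.

    Nested transactions merge into the outermost one, so a level-3
    operation built from level-2 calls still commits a single entry.
    On an exception the outermost transaction rolls the tree back by
    applying the inverses of everything already recorded, then
    re-raises; nothing is committed.  Entries with no records (no-op
    operations) are not committed.
    """
    j = journal_of(tree, journal)
    outer = j._depth == 0
    if outer:
        j._open = CompositeEntry(label)
    j._depth += 1
    try:
        yield j._open
    except BaseException:
        j._depth -= 1
        if outer:
            for rec in reversed(j._open.records):
                rec.inverted().apply(tree)
            j._open = None
        raise
    else:
        j._depth -= 1
        if outer:
            entry, j._open = j._open, None
            if entry.records:
                j.committed.append(entry)
                j.redo_stack.clear()


# ---------------------------------------------------------------------------
# level 1: elementary link operations (validity NOT guaranteed)
# ---------------------------------------------------------------------------

def _check_pair(tree: SwcTree, n: int, n2: int | None) -> None:
    tree[n]
    if n2 is not None:
        tree[n2]
        if n == n2:
            raise SwcError(f"self-link on node {n} is not allowed")


def _write_link(tree: SwcTree, journal: Journal, kind: str, n: int,
                n2: int | None) -> ElementaryOpRecord:
    rec = ElementaryOpRecord(kind, n, getattr(tree[n], _LINK_FIELD[kind]), n2)
    rec.apply(tree)
    journal.record(rec)
    return rec


def link_parent(tree: SwcTree, n: int, n2: int | None = None,
                journal: Journal | None = None) -> ElementaryOpRecord:
    """``f_p``: overwrite the parent link of ``n`` with ``n2`` (or the empty node)."""
    _check_pair(tree, n, n2)
    with op_transaction(tree, f"f_p({n}|{n2})", journal):
        return _write_link(tree, journal_of(tree, journal), "set_parent_link", n, n2)


def link_child(tree: SwcTree, n: int, n2: int | None = None,
               journal: Journal | None = None) -> ElementaryOpRecord:
    """``f_c``: overwrite the first-child link of ``n`` with ``n2``."""
    _check_pair(tree, n, n2)
    with op_transaction(tree, f"f_c({n}|{n2})", journal):
        return _write_link(tree, journal_of(tree, journal), "set_child_link", n, n2)


def link_sibling(tree: SwcTree, n: int, n2: int | None = None,
                 journal: Journal | None = None) -> ElementaryOpRecord:
    """``f_s``: overwrite the next-sibling link of ``n`` with ``n2``."""
    _check_pair(tree, n, n2)
    with op_transaction(tree, f"f_s({n}|{n2})", journal):
        return _write_link(tree, journal_of(tree, journal), "set_sibling_link", n, n2)


# ---------------------------------------------------------------------------
# level 2: simple valid operations
# ---------------------------------------------------------------------------

def is_ancestor(tree: SwcTree, maybe_ancestor: int, node: int) -> bool:
    """True when ``maybe_ancestor`` lies on the parent chain of ``node``
    (a node is its own ancestor)."""
    return bool(tree.upstream_path(node, maybe_ancestor))


def _prev_sibling(tree: SwcTree, n: int) -> int:
    parent = tree[n].parent
    for a, b in zip(kids := tree.children_of(parent), kids[1:]):
        if b == n:
            return a
    raise InvalidTreeError(f"node {n} not found in its parent's sibling chain")


def detach(tree: SwcTree, n: int,
           journal: Journal | None = None) -> list[ElementaryOpRecord]:
    """``F_p0``: set the parent of ``n`` to the empty node, validly.

    Repairs the old parent's child chain first: if ``n`` was the first
    child, the old parent's child link moves to ``n``'s next sibling;
    otherwise the previous sibling's sibling link skips ``n``.  Exactly
    three elementary records are journalled.  Detaching a root is a
    no-op that records nothing.
    """
    node = tree[n]
    if node.parent is None:
        return []
    with op_transaction(tree, f"detach({n})", journal) as entry:
        j = journal_of(tree, journal)
        parent = tree[node.parent]
        recs = []
        if parent.first_child == n:
            recs.append(_write_link(tree, j, "set_child_link",
                                    parent.id, node.next_sibling))
        else:
            recs.append(_write_link(tree, j, "set_sibling_link",
                                    _prev_sibling(tree, n), node.next_sibling))
        recs.append(_write_link(tree, j, "set_parent_link", n, None))
        recs.append(_write_link(tree, j, "set_sibling_link", n, None))
        return recs


def set_parent(tree: SwcTree, n: int, n2: int,
               journal: Journal | None = None) -> list[ElementaryOpRecord]:
    """``F_p``: make ``n`` the *first* child of ``n2``.

    Composition: detach ``n``, point its parent link at ``n2``, splice
    it in front of ``n2``'s former first child.  Rejected with
    :class:`LoopError` (before any mutation) when ``n2`` is ``n`` or a
    descendant of ``n``, because attaching would close a parent-link
    cycle.
    """
    tree[n]
    tree[n2]
    if n == n2 or is_ancestor(tree, n, n2):
        raise LoopError(f"cannot attach {n} under its own descendant {n2}")
    with op_transaction(tree, f"set_parent({n}|{n2})", journal):
        j = journal_of(tree, journal)
        recs = detach(tree, n, journal)
        old_first = tree[n2].first_child
        recs.append(_write_link(tree, j, "set_parent_link", n, n2))
        recs.append(_write_link(tree, j, "set_sibling_link", n, old_first))
        recs.append(_write_link(tree, j, "set_child_link", n2, n))
        return recs


def set_sibling(tree: SwcTree, n: int, n2: int,
                journal: Journal | None = None) -> list[ElementaryOpRecord]:
    """``F_s``: insert ``n2`` as the next sibling of ``n``.

    ``n2`` is detached first (its own subtree stays attached beneath
    it), then rethreaded with ``P(n2) = P(n)`` and spliced into the
    sibling chain after ``n``.  Errors: ``n`` is a root (no parent to
    share), or ``n2`` is an ancestor of ``n``'s parent (would loop).
    """
    node = tree[n]
    tree[n2]
    if n == n2:
        raise SwcError(f"cannot make node {n} a sibling of itself")
    if node.parent is None:
        raise SwcError(f"node {n} is a root and has no sibling chain")
    if is_ancestor(tree, n2, node.parent):
        raise LoopError(f"inserting {n2} as sibling of {n} would create a loop")
    with op_transaction(tree, f"set_sibling({n}|{n2})", journal):
        j = journal_of(tree, journal)
        recs = detach(tree, n2, journal)
        recs.append(_write_link(tree, j, "set_parent_link", n2, tree[n].parent))
        recs.append(_write_link(tree, j, "set_sibling_link", n2, tree[n].next_sibling))
        recs.append(_write_link(tree, j, "set_sibling_link", n, n2))
        return recs


# ---------------------------------------------------------------------------
# undo / redo
# ---------------------------------------------------------------------------

def undo(tree: SwcTree, journal: Journal | None = None) -> bool:
    """Revert the last committed operation; ``False`` when history is empty."""
    return journal_of(tree, journal).undo(tree)


def redo(tree: SwcTree, journal: Journal | None = None) -> bool:
    """Re-apply the last undone operation; ``False`` when there is none."""
    return journal_of(tree, journal).redo(tree)
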