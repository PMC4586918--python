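"""High-level (level-3) editing operations on SWC trees.

These are the composite edits a tracer actually invokes while proofing
a reconstruction: geometric fixes (move, resize, interpolate, remove a
turn), topology repairs (connect fragments by their minimum spanning
tree, set / reset a branch point, resolve a crossover), and node
lifecycle (extend a branch, delete a selection).  Every operation is
built from the level-2 algebra in :mod:`swcedit.ops`, so each one is a
single journal entry, undoable in one step, and leaves the tree
structurally valid.

Angle conventions: angles are measured in degrees between direction
vectors anchored at the node under edit; all angular ties are broken by
the smallest node id so results are reproducible.  Degree counts the
parent edge plus the child edges (a root with one child has degree 1).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .model import SwcError, SwcTree, UnknownNodeError
from .ops import (CreateNodeRecord, DeleteNodeRecord, GeometryOpRecord,
                  Journal, LoopError, detach, journal_of, op_transaction,
                  set_parent)

__all__ = [
    "EditError",
    "Selection",
    "CrossoverResult",
    "move_node",
    "set_radius",
    "extend_branch",
    "delete_nodes",
    "interpolate_nodes",
    "connect_nodes_mst",
    "set_branch_point",
    "reset_branch_point",
    "remove_turn",
    "resolve_crossover",
    "reroot",
]


class EditError(SwcError):
    """An editing operation could not be applied to the given nodes."""


class Selection:
    """An ordered, duplicate-free set of node ids naming an edit's input."""

    def __init__(self, node_ids) -> None:
        seen: set[int] = set()
        self.node_ids: list[int] = []
        for nid in node_ids:
            nid = int(nid)
            if nid not in seen:
                seen.add(nid)
                self.node_ids.append(nid)

    def __iter__(self):
        return iter(self.node_ids)

    def __len__(self) -> int:
        return len(self.node_ids)

    def validate(self, tree: SwcTree) -> None:
        for nid in self.node_ids:
            if nid not in tree:
                raise UnknownNodeError(f"selection references absent node {nid}")


def _selection(tree: SwcTree, sel) -> Selection:
    sel = sel if isinstance(sel, Selection) else Selection(sel)
    sel.validate(tree)
    return sel


def _neighbors(tree: SwcTree, n: int) -> list[int]:
    node = tree[n]
    out = [] if node.parent is None else [node.parent]
    out.extend(tree.children_of(n))
    return out


def _unit(v: np.ndarray) -> np.ndarray:
    norm = float(np.linalg.norm(v))
    return v / norm if norm > 0 else np.array([1.0, 0.0, 0.0])


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two vectors in degrees, in [0, 180]."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 180.0  # degenerate: treat as straight, never the sharpest pair
    c = float(np.dot(u, v) / (nu * nv))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


# ---------------------------------------------------------------------------
# geometric edits
# ---------------------------------------------------------------------------

def move_node(tree: SwcTree, n: int, new_center,
              journal: Journal | None = None) -> None:
    """Move a node's centre; links are untouched."""
    node = tree[n]
    new_center = np.asarray(new_center, dtype=float)
    if new_center.shape != (3,) or not np.all(np.isfinite(new_center)):
        raise EditError("new centre must be a finite 3-vector")
    with op_transaction(tree, f"move({n})", journal):
        rec = GeometryOpRecord(n, tuple(node.center), node.radius,
                               tuple(new_center), node.radius)
        rec.apply(tree)
        journal_of(tree, journal).record(rec)


def set_radius(tree: SwcTree, n: int, r: float,
               journal: Journal | None = None) -> None:
    """Set a node's radius; must be strictly positive."""
    node = tree[n]
    r = float(r)
    if not (r > 0 and math.isfinite(r)):
        raise EditError(f"radius must be positive, got {r}")
    with op_transaction(tree, f"radius({n})", journal):
        rec = GeometryOpRecord(n, tuple(node.center), node.radius,
                               tuple(node.center), r)
        rec.apply(tree)
        journal_of(tree, journal).record(rec)


def remove_turn(tree: SwcTree, n: int, journal: Journal | None = None) -> bool:
    """Flatten a sharp turn at ``n`` by midpointing its sharpest flank pair.

    A turn is three sequentially connected nodes forming an acute angle
    at the middle one.  Among all pairs of ``n``'s neighbours the pair
    forming the smallest angle at ``n`` is the flank pair; if that angle
    is below 90 degrees the node is moved to the flank midpoint with the
    averaged flank radius (purely geometric) and ``True`` is returned,
    otherwise the node is not a turn and nothing changes.
    """
    nbrs = _neighbors(tree, n)
    if len(nbrs) < 2:
        raise EditError(f"node {n} needs at least two neighbours to be a turn")
    center = tree[n].center
    best: tuple[float, int, int] | None = None
    for a, b in itertools.combinations(sorted(nbrs), 2):
        ang = _angle_deg(tree[a].center - center, tree[b].center - center)
        if best is None or (ang, a, b) < best:
            best = (ang, a, b)
    ang, a, b = best
    if ang >= 90.0:
        return False
    na, nb = tree[a], tree[b]
    with op_transaction(tree, f"remove_turn({n})", journal):
        rec = GeometryOpRecord(n, tuple(center), tree[n].radius,
                               tuple((na.center + nb.center) / 2.0),
                               (na.radius + nb.radius) / 2.0)
        rec.apply(tree)
        journal_of(tree, journal).record(rec)
    return True


def interpolate_nodes(tree: SwcTree, sel,
                      journal: Journal | None = None) -> list[list[int]]:
    """Linearly interpolate selected runs between their unselected anchors.

    Within each maximal run of ``k`` consecutive selected nodes along a
    path, flanked by unselected anchor nodes ``a`` (upstream) and ``b``
    (downstream), node ``j`` (1-based) receives centre and radius
    ``a + (j / (k+1)) * (b - a)`` componentwise.  The parameter is the
    index fraction, not arclength, so the result is independent of
    pre-edit geometry noise.  Topology never changes.

    Runs that touch a terminus or a root (no anchor on one end) or that
    contain a branch point are skipped and returned for reporting.
    """
    sel = _selection(tree, sel)
    selected = set(sel.node_ids)
    runs: list[list[int]] = []
    skipped: list[list[int]] = []

    for nid in sel.node_ids:
        parent = tree[nid].parent
        if parent is not None and parent in selected:
            continue  # not the start of a run
        run = [nid]
        ok = parent is not None
        cur = nid
        anchor_b = None
        while True:
            kids = tree.children_of(cur)
            if len(kids) != 1:
                ok = False  # terminus (0 children) or branch point (>1)
                break
            nxt = kids[0]
            if nxt in selected:
                run.append(nxt)
                cur = nxt
            else:
                anchor_b = nxt
                break
        (runs if ok and anchor_b is not None else skipped).append(run)

    if not runs:
        return skipped

    with op_transaction(tree, "interpolate", journal):
        j = journal_of(tree, journal)
        for run in runs:
            a = tree[tree[run[0]].parent]
            b = tree[tree.children_of(run[-1])[0]]
            va = np.append(a.center, a.radius)
            vb = np.append(b.center, b.radius)
            k = len(run)
            for idx, nid in enumerate(run, start=1):
                v = va + (idx / (k + 1)) * (vb - va)
                node = tree[nid]
                rec = GeometryOpRecord(nid, tuple(node.center), node.radius,
                                       tuple(v[:3]), float(v[3]))
                rec.apply(tree)
                j.record(rec)
    return skipped


# ---------------------------------------------------------------------------
# node lifecycle
# ---------------------------------------------------------------------------

def extend_branch(tree: SwcTree, n: int, point,
                  journal: Journal | None = None) -> int:
    """Grow a new node at ``point`` as the first child of ``n``.

    The new node inherits the radius and type code of ``n``; its id is
    the smallest unused id above the current maximum.  Returns the new
    id.  Undo removes the node entirely.
    """
    node = tree[n]
    point = np.asarray(point, dtype=float)
    with op_transaction(tree, f"extend({n})", journal):
        new_id = tree.next_id()
        rec = CreateNodeRecord(new_id, node.type_code, tuple(point), node.radius)
        rec.apply(tree)
        journal_of(tree, journal).record(rec)
        set_parent(tree, new_id, n, journal)
    return new_id


def delete_nodes(tree: SwcTree, sel, journal: Journal | None = None) -> None:
    """Remove the selected nodes; orphaned children become roots.

    Each surviving child of a removed node is detached (it keeps its own
    subtree), so deleting an interior node splits the component rather
    than bridging across the gap.  One journal entry; undo resurrects
    every node with its links.
    """
    sel = _selection(tree, sel)
    if not len(sel):
        return
    with op_transaction(tree, "delete", journal):
        j = journal_of(tree, journal)
        for nid in sel.node_ids:
            for child in tree.children_of(nid):
                detach(tree, child, journal)
            detach(tree, nid, journal)
            node = tree[nid]
            rec = DeleteNodeRecord(nid, node.type_code, tuple(node.center),
                                   node.radius)
            rec.apply(tree)
            j.record(rec)


# ---------------------------------------------------------------------------
# topology repairs
# ---------------------------------------------------------------------------

def reroot(tree: SwcTree, n: int, journal: Journal | None = None) -> None:
    """Make ``n`` the root of its component by reversing its parent chain."""
    path = tree.upstream_path(n, tree.root_of(n))
    if len(path) == 1:
        return
    with op_transaction(tree, f"reroot({n})", journal):
        detach(tree, n, journal)
        prev = n
        for nid in path[1:]:
            set_parent(tree, nid, prev, journal)
            prev = nid


def _prim_mst(points: np.ndarray, ids: list[int]) -> list[tuple[int, int]]:
    """Prim's MST over the complete Euclidean graph on ``points``.

    Returns edges as (id, id) pairs.  Deterministic: growth starts at
    the smallest id, ties on edge weight are broken by the candidate
    node's id and attachment source id.  Zero-length edges (co-located
    nodes) are ordinary edges here.
    """
    order = sorted(range(len(ids)), key=lambda i: ids[i])
    n = len(ids)
    diff = points[:, None, :] - points[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    start = order[0]
    in_tree = {start}
    best_w = dist[start].copy()
    best_from = np.full(n, start)
    edges: list[tuple[int, int]] = []
    for _ in range(n - 1):
        cand = min((i for i in range(n) if i not in in_tree),
                   key=lambda i: (best_w[i], ids[i]))
        edges.append((ids[best_from[cand]], ids[cand]))
        in_tree.add(cand)
        for i in range(n):
            if i in in_tree:
                continue
            w = dist[cand, i]
            if w < best_w[i] or (w == best_w[i] and ids[cand] < ids[best_from[i]]):
                best_w[i] = w
                best_from[i] = cand
    return edges


def connect_nodes_mst(tree: SwcTree, sel,
                      journal: Journal | None = None) -> list[tuple[int, int]]:
    """Connect the selected nodes along their minimum spanning tree.

    Builds the complete graph on the selected nodes with Euclidean
    centre-to-centre edge weights, computes its MST, and realises every
    MST edge whose endpoints currently lie in different connected
    components of the neuron: the smaller component is re-rooted at its
    endpoint and attached under the other endpoint (ties on size go to
    the endpoint with the larger id).  Edges inside one component are
    skipped -- connecting them would close a loop.  Returns the list of
    (parent_endpoint, attached_endpoint) connections actually made.
    """
    sel = _selection(tree, sel)
    if len(sel) < 2:
        raise EditError("connecting nodes needs at least two selected nodes")
    ids = sel.node_ids
    points = np.array([tree[i].center for i in ids])
    mst_edges = _prim_mst(points, ids)
    centers = {i: tree[i].center for i in ids}
    mst_edges.sort(key=lambda e: (float(np.linalg.norm(centers[e[0]] - centers[e[1]])),
                                  min(e), max(e)))
    made: list[tuple[int, int]] = []
    with op_transaction(tree, "connect_mst", journal):
        for u, v in mst_edges:
            comp_u = tree.component_of(u)
            if v in comp_u:
                continue
            comp_v = tree.component_of(v)
            if (len(comp_u), -u) < (len(comp_v), -v):
                child, parent = u, v
            else:
                child, parent = v, u
            reroot(tree, child, journal)
            set_parent(tree, child, parent, journal)
            made.append((parent, child))
    return made


def set_branch_point(tree: SwcTree, n: int,
                     journal: Journal | None = None) -> int:
    """Attach the nearest free end of another component under ``n``.

    Looks at the terminal nodes (total degree <= 1) of every connected
    component other than ``n``'s, picks the one closest to ``n``
    (Euclidean, ties by smaller id), re-roots its component there and
    attaches it under ``n``.  Applied only when the connection creates a
    branch point, i.e. when ``n`` already has degree >= 2.  Returns the
    attached terminus id.
    """
    comp = tree.component_of(n)
    if tree.degree(n) < 2:
        raise EditError(
            f"connecting to node {n} would not create a branch point")
    candidates = [t.id for t in tree
                  if t.id not in comp and tree.degree(t.id) <= 1]
    if not candidates:
        raise EditError("no isolated branch end available to connect")
    center = tree[n].center
    target = min(candidates,
                 key=lambda t: (float(np.linalg.norm(tree[t].center - center)), t))
    with op_transaction(tree, f"set_branch_point({n})", journal):
        reroot(tree, target, journal)
        set_parent(tree, target, n, journal)
    return target


def _walk_to_branch_point(tree: SwcTree, n: int) -> tuple[int, int] | None:
    """Nearest branch point along the segment through ``n``.

    Walks from ``n`` in each neighbour direction through degree-2 chain
    nodes until a node of degree >= 3 is met.  Returns ``(b, u)`` where
    ``u`` is ``b``'s neighbour on the path back towards ``n``; ``None``
    when both directions dead-end.  Ties on path length go to the
    smaller branch-point id.
    """
    found: list[tuple[int, int, int]] = []  # (steps, b, u)
    for start in _neighbors(tree, n):
        prev, cur, steps = n, start, 1
        while True:
            if tree.degree(cur) >= 3:
                found.append((steps, cur, prev))
                break
            nxt = [m for m in _neighbors(tree, cur) if m != prev]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            steps += 1
    if not found:
        return None
    steps, b, u = min(found)
    return b, u


def reset_branch_point(tree: SwcTree, n: int,
                       journal: Journal | None = None) -> int:
    """Move the neighbouring branching structure onto ``n``.

    Finds the branch point ``b`` (degree >= 3) nearest to ``n`` along
    the segment containing ``n``, then among ``b``'s incident branches
    -- excluding the one leading back to ``n`` -- picks the branch whose
    direction at ``b`` deviates most from a straight continuation of the
    segment (i.e. the most perpendicular one; ties by smaller id) and
    re-attaches it at ``n``.  ``b``'s degree drops by one.  Returns the
    id of the moved branch's attachment node.
    """
    hit = _walk_to_branch_point(tree, n)
    if hit is None:
        raise EditError(f"no branch point adjacent to node {n} along its segment")
    b, u = hit
    through = tree[u].center - tree[b].center
    candidates = [w for w in _neighbors(tree, b) if w != u]
    scored = sorted(
        ((-(180.0 - _angle_deg(through, tree[w].center - tree[b].center)), w)
         for w in candidates))
    w = scored[0][1]
    with op_transaction(tree, f"reset_branch_point({n})", journal):
        if tree[w].parent == b:
            set_parent(tree, w, n, journal)
        else:  # w is b's parent: move the upstream branch
            detach(tree, b, journal)
            reroot(tree, w, journal)
            set_parent(tree, w, n, journal)
    return w


# ---------------------------------------------------------------------------
# crossover resolution
# ---------------------------------------------------------------------------

@dataclass
class CrossoverResult:
    """Outcome of :func:`resolve_crossover`."""

    pairs: list[tuple[int, int]]       # arm head ids, paired into through-paths
    unpaired: int | None               # leftover arm when the hub degree is odd
    new_node_ids: list[int]            # co-located duplicates of the hub


def _pairings(items: list[int]):
    """All pairings of ``items`` in lexicographic order (items sorted).

    For an odd count, every choice of one leftover element is
    enumerated (ascending) with the pairings of the rest.  Yields
    ``(pairs, leftover)``.
    """
    def perfect(rest: tuple[int, ...]):
        if not rest:
            yield []
            return
        first, tail = rest[0], rest[1:]
        for k, partner in enumerate(tail):
            for sub in perfect(tail[:k] + tail[k + 1:]):
                yield [(first, partner)] + sub

    items = sorted(items)
    if len(items) % 2 == 0:
        for pairs in perfect(tuple(items)):
            yield pairs, None
    else:
        for i, leftover in enumerate(items):
            rest = tuple(items[:i] + items[i + 1:])
            for pairs in perfect(rest):
                yield pairs, leftover


def resolve_crossover(tree: SwcTree, n: int,
                      journal: Journal | None = None) -> CrossoverResult:
    """Split a crossover hub into independently continuing paths.

    A crossover is a tracing artefact where two (or more) passing
    branches were wrongly joined at a single node of degree >= 4.  The
    hub's incident arms are paired so that each pair continues as
    straight as possible: over all pairings, minimise the sum per pair
    of ``180 deg - angle`` between the two arm directions at the hub
    (an exact, exhaustive minimisation; ties resolved by the smallest
    lexicographic pairing of arm ids; with an odd arm count the
    leftover arm stays on the hub).  Each pair is rebuilt as one
    continuous path through its own copy of the hub; the copies are
    co-located with distinct ids, so the paths cross in space without
    sharing a node.  For an even hub the node count grows by
    (number of pairs - 1).
    """
    arms = _neighbors(tree, n)
    if len(arms) < 4:
        raise EditError(f"node {n} has degree {len(arms)}: no crossover here")
    hub = tree[n]
    dirs = {a: _unit(tree[a].center - hub.center) for a in arms}

    def cost(pairs: list[tuple[int, int]]) -> float:
        return sum(180.0 - _angle_deg(dirs[a], dirs[b]) for a, b in pairs)

    best_pairs, best_left, best_cost = None, None, math.inf
    for pairs, leftover in _pairings(arms):
        c = cost(pairs)
        if c < best_cost - 1e-12:
            best_pairs, best_left, best_cost = pairs, leftover, c

    parent_arm = hub.parent
    new_ids: list[int] = []
    with op_transaction(tree, f"resolve_crossover({n})", journal):
        j = journal_of(tree, journal)
        for child in tree.children_of(n):
            detach(tree, child, journal)

        def orient_inward(arm: int) -> None:
            # Reverse the arm's internal orientation so its head can accept
            # a child without turning into a spurious branch point.
            first = tree[arm].first_child
            if first is not None:
                reroot(tree, first, journal)

        hub_pair = None
        for pair in best_pairs:
            if parent_arm is not None and parent_arm in pair:
                hub_pair = pair
                break
        if hub_pair is None and parent_arm is None and best_pairs:
            hub_pair = best_pairs[0]

        for pair in best_pairs:
            a, b = sorted(pair)
            if pair is hub_pair:
                if parent_arm in pair:
                    other = b if a == parent_arm else a
                    set_parent(tree, other, n, journal)
                else:  # hub is a root: thread it into the pair's path
                    set_parent(tree, a, n, journal)
                    orient_inward(b)
                    set_parent(tree, n, b, journal)
            else:
                dup = tree.next_id()
                rec = CreateNodeRecord(dup, hub.type_code, tuple(hub.center),
                                       hub.radius)
                rec.apply(tree)
                j.record(rec)
                new_ids.append(dup)
                orient_inward(b)
                set_parent(tree, dup, b, journal)
                set_parent(tree, a, dup, journal)
        if best_left is not None and best_left != parent_arm:
            set_parent(tree, best_left, n, journal)
    return CrossoverResult(pairs=[tuple(sorted(p)) for p in best_pairs],
                           unpaired=best_left, new_node_ids=new_ids)
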