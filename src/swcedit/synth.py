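"""Synthetic fixtures: random trees, tubular phantoms, perturbed copies.

Everything downstream of the data model is testable without external
data through three generators:

* :func:`generate_random_tree` grows a valid random tree by a
  branching random walk -- the stand-in for a traced neuron;
* :func:`render_tree_volume` rasterises a tree into a 3D intensity
  grid as capsules (cylinders with spherical caps) on a constant
  background, optionally with Gaussian noise -- the stand-in for a
  microscope stack;
* :func:`perturb_tree` emulates the error modes of a human tracing:
  isotropic jitter of node positions, dropped terminal branches and
  spurious short branches.

All randomness flows from a single integer seed per call (no global
state), so fixtures are bit-reproducible.  :func:`random_edit` applies
one randomly chosen level-2/3 operation to a tree -- the driver used by
the validity and undo stress properties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import edits
from .model import SwcError, SwcNode, SwcTree, validate_tree
from .ops import detach, set_parent, set_sibling
from .trace import VolumeImage

__all__ = [
    "TreeGenParams",
    "PerturbParams",
    "generate_random_tree",
    "render_tree_volume",
    "perturb_tree",
    "random_edit",
]


@dataclass
class TreeGenParams:
    """Knobs of the random-walk tree generator.

    ``n_nodes`` total nodes; ``branch_prob`` chance per growth step that
    the extended tip also stays active (a bifurcation); ``step_length``
    edge length in coordinate units; ``radius_range`` uniform node
    radius bounds; ``wobble_deg`` direction jitter per step in degrees;
    ``seed`` drives all randomness.
    """

    n_nodes: int = 40
    branch_prob: float = 0.1
    step_length: float = 5.0
    radius_range: tuple[float, float] = (0.5, 2.0)
    wobble_deg: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise SwcError("n_nodes must be >= 1")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise SwcError("branch_prob must lie in [0, 1]")
        if self.step_length <= 0 or self.wobble_deg < 0:
            raise SwcError("step_length must be positive, wobble_deg >= 0")
        lo, hi = self.radius_range
        if not 0 < lo <= hi:
            raise SwcError("radius_range must satisfy 0 < min <= max")


@dataclass
class PerturbParams:
    """Error modes applied by :func:`perturb_tree`.

    ``sigma_pos`` SD of the isotropic Gaussian displacement of every
    node centre; ``p_drop_terminal_branch`` chance of deleting each
    terminal branch; ``p_spurious_branch`` Poisson rate of short fake
    branches grafted at random nodes; ``seed`` drives all randomness.
    """

    sigma_pos: float = 0.0
    p_drop_terminal_branch: float = 0.0
    p_spurious_branch: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_pos < 0 or self.p_spurious_branch < 0:
            raise SwcError("sigma_pos and p_spurious_branch must be >= 0")
        if not 0.0 <= self.p_drop_terminal_branch <= 1.0:
            raise SwcError("p_drop_terminal_branch must lie in [0, 1]")


def _wobbled(rng: np.random.Generator, direction: np.ndarray,
             wobble_deg: float) -> np.ndarray:
    jitter = rng.normal(0.0, np.sin(np.radians(max(wobble_deg, 1e-9))), 3)
    v = direction + jitter
    norm = np.linalg.norm(v)
    return v / norm if norm > 0 else direction


def generate_random_tree(params: TreeGenParams) -> SwcTree:
    """Grow a valid random tree by a branching random walk.

    Starts with one root at the origin heading in a random direction;
    each step extends a randomly chosen active tip by ``step_length``
    along a wobbled direction, and with probability ``branch_prob`` the
    old tip stays active too (creating a branch point).  With
    ``branch_prob = 0`` the result is a chain.  Deterministic per seed.
    """
    rng = np.random.default_rng(params.seed)
    lo, hi = params.radius_range
    tree = SwcTree()
    root = SwcNode(1, 3, (0.0, 0.0, 0.0), rng.uniform(lo, hi))
    tree.add(root)
    direction = _wobbled(rng, np.array([1.0, 0.0, 0.0]), 90.0)
    tips: list[tuple[int, np.ndarray]] = [(1, direction)]
    while len(tree) < params.n_nodes:
        k = int(rng.integers(len(tips)))
        tip_id, tip_dir = tips[k]
        new_dir = _wobbled(rng, tip_dir, params.wobble_deg)
        nid = tree.next_id()
        tree.add(SwcNode(nid, 3, tree[tip_id].center + params.step_length * new_dir,
                         rng.uniform(lo, hi)))
        set_parent(tree, nid, tip_id)
        if rng.random() < params.branch_prob:
            # the old tip keeps growing in a freshly wobbled direction
            tips[k] = (tip_id, _wobbled(rng, tip_dir, max(params.wobble_deg, 30.0)))
            tips.append((nid, new_dir))
        else:
            tips[k] = (nid, new_dir)
    tree.journal = None  # construction history is not part of the fixture
    _validate_or_raise(tree)
    return tree


def render_tree_volume(tree: SwcTree, shape, foreground: float = 200.0,
                       background: float = 10.0, noise_sd: float = 0.0,
                       seed: int = 0) -> VolumeImage:
    """Rasterise a tree into an intensity volume as capsules.

    Every edge becomes a capsule whose radius interpolates linearly
    between its endpoint radii (isolated nodes become spheres); voxels
    inside any capsule are set to ``foreground``, the rest to
    ``background``.  Gaussian noise of SD ``noise_sd`` is then added and
    the result clipped to [0, 255] (the 8-bit intensity range used by
    the TIFF writer).  Deterministic per seed.  Raises when the tree,
    inflated by its radii, does not fit the shape.
    """
    shape = tuple(int(s) for s in shape)
    vol = np.full(shape, float(background))
    mask = np.zeros(shape, dtype=bool)
    bounds = np.array(shape, dtype=float)
    for node in tree:
        if np.any(node.center - node.radius < -0.5) or \
           np.any(node.center + node.radius > bounds - 0.5):
            raise SwcError(f"node {node.id} (with radius) outside volume {shape}")

    def stamp_capsule(pa, ra, pb, rb):
        rmax = max(ra, rb)
        lo = np.floor(np.minimum(pa, pb) - rmax).astype(int)
        hi = np.ceil(np.maximum(pa, pb) + rmax).astype(int)
        lo = np.clip(lo, 0, np.array(shape) - 1)
        hi = np.clip(hi, 0, np.array(shape) - 1)
        xs, ys, zs = (np.arange(lo[i], hi[i] + 1) for i in range(3))
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        pts = np.stack([gx, gy, gz], axis=-1).astype(float)
        ab = pb - pa
        denom = float(np.dot(ab, ab))
        if denom == 0:
            t = np.zeros(pts.shape[:-1])
        else:
            t = np.clip(np.einsum("...k,k->...", pts - pa, ab) / denom, 0.0, 1.0)
        closest = pa + t[..., None] * ab
        dist = np.linalg.norm(pts - closest, axis=-1)
        rad = ra + t * (rb - ra)
        sub = dist <= rad
        mask[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] |= sub

    for node in tree:
        if node.parent is None:
            if tree[node.id].first_child is None:
                stamp_capsule(node.center, node.radius, node.center, node.radius)
        else:
            p = tree[node.parent]
            stamp_capsule(p.center, p.radius, node.center, node.radius)

    vol[mask] = float(foreground)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vol = vol + rng.normal(0.0, noise_sd, shape)
    return VolumeImage(np.clip(vol, 0.0, 255.0))


def _terminal_branches(tree: SwcTree) -> list[list[int]]:
    """Maximal leaf-ending chains below the nearest branch point.

    For each leaf terminus, the branch contains the leaf and its
    ancestors while each has a single child, stopping before a branch
    point (>= 2 children) and before a root.
    """
    branches = []
    for nid in sorted(tree.ids()):
        if tree.children_of(nid) or tree[nid].parent is None:
            continue
        branch = [nid]
        cur = tree[nid].parent
        while cur is not None and tree[cur].parent is not None \
                and len(tree.children_of(cur)) == 1:
            branch.append(cur)
            cur = tree[cur].parent
        branches.append(branch)
    return branches


def perturb_tree(tree: SwcTree, params: PerturbParams) -> SwcTree:
    """A noise-perturbed copy of a tree (the original is untouched).

    Applies, in order: isotropic Gaussian jitter of every node centre,
    random dropping of whole terminal branches, and grafting of
    Poisson-many short spurious branches at random nodes.  With all
    parameters zero the copy is identical; with only ``sigma_pos`` set
    the topology (and hence the critical-point count) is preserved.
    """
    rng = np.random.default_rng(params.seed)
    out = tree.copy()

    if params.sigma_pos > 0:
        for nid in sorted(out.ids()):
            out[nid].center = out[nid].center + rng.normal(0.0, params.sigma_pos, 3)

    if params.p_drop_terminal_branch > 0:
        doomed: list[int] = []
        for branch in _terminal_branches(out):
            if rng.random() < params.p_drop_terminal_branch:
                doomed.extend(branch)
        if doomed:
            edits.delete_nodes(out, doomed)

    if params.p_spurious_branch > 0 and len(out):
        n_spur = int(rng.poisson(params.p_spurious_branch))
        edge_lens = [float(np.linalg.norm(out[n.id].center - out[n.parent].center))
                     for n in out if n.parent is not None]
        step = float(np.mean(edge_lens)) if edge_lens else 3.0
        ids = sorted(out.ids())
        for _ in range(n_spur):
            host = ids[int(rng.integers(len(ids)))]
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction) or 1.0
            prev = host
            for k in range(int(rng.integers(2, 4))):
                point = out[prev].center + step * direction
                prev = edits.extend_branch(out, prev, point)

    out.journal = None
    _validate_or_raise(out)
    return out


# ---------------------------------------------------------------------------
# random operation driver (stress fixture)
# ---------------------------------------------------------------------------

def random_edit(tree: SwcTree, rng: np.random.Generator) -> str:
    """Apply one randomly chosen level-2/3 operation with random arguments.

    Operations whose preconditions reject the drawn arguments (loop
    guards, degree requirements, missing components...) count as clean
    no-ops.  Returns a short label of what was attempted, for
    diagnostics.  The tree is left valid either way -- that is the
    property the stress suites check.
    """
    ids = sorted(tree.ids())
    if not ids:
        return "noop(empty)"
    pick = lambda: ids[int(rng.integers(len(ids)))]
    op = rng.integers(12)
    try:
        if op == 0:
            detach(tree, pick())
            return "detach"
        if op == 1:
            set_parent(tree, pick(), pick())
            return "set_parent"
        if op == 2:
            set_sibling(tree, pick(), pick())
            return "set_sibling"
        if op == 3:
            edits.move_node(tree, pick(), rng.normal(0, 20, 3))
            return "move_node"
        if op == 4:
            edits.set_radius(tree, pick(), float(rng.uniform(0.2, 4.0)))
            return "set_radius"
        if op == 5:
            edits.extend_branch(tree, pick(), rng.normal(0, 20, 3))
            return "extend_branch"
        if op == 6:
            k = int(rng.integers(1, min(4, len(ids)) + 1))
            sel = list(rng.choice(ids, size=k, replace=False))
            if len(sel) < len(tree):  # keep the fixture nonempty
                edits.delete_nodes(tree, sel)
            return "delete_nodes"
        if op == 7:
            k = int(rng.integers(2, min(6, len(ids)) + 1)) if len(ids) >= 2 else 2
            sel = list(rng.choice(ids, size=min(k, len(ids)), replace=False))
            if len(sel) >= 2:
                edits.connect_nodes_mst(tree, sel)
            return "connect_mst"
        if op == 8:
            edits.set_branch_point(tree, pick())
            return "set_branch_point"
        if op == 9:
            edits.reset_branch_point(tree, pick())
            return "reset_branch_point"
        if op == 10:
            edits.remove_turn(tree, pick())
            return "remove_turn"
        if op == 11:
            edits.resolve_crossover(tree, pick())
            return "resolve_crossover"
    except (edits.EditError, SwcError):
        return "rejected"
    return "noop"


def _validate_or_raise(tree: SwcTree) -> None:
    report = validate_tree(tree)
    if not report.is_valid:  # pragma: no cover - defensive
        raise SwcError(f"generator produced invalid tree: {report.summary()}")
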