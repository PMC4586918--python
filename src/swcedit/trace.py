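"""Image-dependent node creation: ray seeding and geodesic path tracing.

Two interactions need the raw image rather than the tree alone:

* **Seeding** -- a mouse click in a 3D view defines a ray through the
  volume; the seed is the first location of maximum intensity along
  that ray (:func:`seed_from_ray`).
* **Point-to-point tracing** -- connecting two nodes through signal:
  the minimal-cost ("geodesic") path on the 26-connected voxel graph,
  where the cost of a step shrinks exponentially with the intensity it
  passes through, so optimal paths hug bright voxels.  The voxel path
  is resampled to an even node spacing and turned into journalled SWC
  nodes (:func:`connect_by_tracing`).

The edge weight between neighbouring voxels ``u`` and ``v`` is::

    w(u, v) = step_length(u, v) * exp(-alpha * ((I(u) + I(v)) / 2) / I_max)

with ``step_length`` the Euclidean step in ``voxel_size`` units and
``I_max`` the volume maximum (a zero-signal volume degrades to plain
Euclidean shortest paths).  ``alpha`` (default 5) controls how strongly
brightness is preferred over straightness.  These choices -- like the
resampling spacing (default 3 voxels) and the shell-based radius
estimator -- are configurable stand-ins for the tracing internals,
which are not pinned down by the editing algebra itself.

Volumes are stored x-fastest: ``intensities[x, y, z]``.  TIFF stacks
(page order z, y, x) are transposed on read.  Node coordinates live in
voxel-index space with the centre of voxel (0, 0, 0) at the origin.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .model import SwcError, SwcTree
from .ops import (CreateNodeRecord, Journal, journal_of, op_transaction,
                  set_parent)
from .edits import reroot

__all__ = [
    "TraceError",
    "VolumeImage",
    "Ray",
    "PathTrace",
    "read_volume",
    "write_volume",
    "seed_from_ray",
    "geodesic_path",
    "resample_path",
    "estimate_radius",
    "connect_by_tracing",
]

DEFAULT_ALPHA = 5.0
DEFAULT_SPACING = 3.0


class TraceError(SwcError):
    """An image-dependent operation could not be carried out."""


@dataclass
class VolumeImage:
    """A 3D scalar intensity grid with voxel spacing.

    ``intensities`` is indexed ``[x, y, z]`` and must be finite and
    nonnegative; ``voxel_size`` scales step lengths (and therefore path
    costs) per axis.
    """

    intensities: np.ndarray
    voxel_size: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3 or min(self.intensities.shape) < 1:
            raise TraceError("volume must be a non-empty 3D grid")
        if not np.all(np.isfinite(self.intensities)) or self.intensities.min() < 0:
            raise TraceError("intensities must be finite and nonnegative")
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        if self.voxel_size.shape != (3,) or np.any(self.voxel_size <= 0):
            raise TraceError("voxel_size must be three positive reals")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def contains_index(self, idx) -> bool:
        idx = np.asarray(idx)
        return bool(np.all(idx >= 0) and np.all(idx < self.shape))

    def nearest_voxel(self, point) -> tuple[int, int, int]:
        """Index of the voxel whose centre is nearest to ``point`` (clipped)."""
        idx = np.rint(np.asarray(point, dtype=float)).astype(int)
        idx = np.clip(idx, 0, np.array(self.shape) - 1)
        return tuple(int(v) for v in idx)


@dataclass
class Ray:
    """A half-line through the volume: origin plus unit direction."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = float(np.linalg.norm(self.direction))
        if norm == 0:
            raise TraceError("ray direction must be nonzero")
        if abs(norm - 1.0) > 1e-9:
            self.direction = self.direction / norm


@dataclass
class PathTrace:
    """A traced voxel path: indices, accumulated cost, resampled nodes."""

    voxel_path: list[tuple[int, int, int]]
    cost: float
    resampled_nodes: list[tuple[np.ndarray, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------

def read_volume(path, voxel_size=(1.0, 1.0, 1.0)) -> VolumeImage:
    """Read an 8/16-bit grayscale TIFF stack (page order z, y, x)."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise TraceError(f"expected a grayscale stack, got shape {arr.shape}")
    return VolumeImage(np.ascontiguousarray(arr.transpose(2, 1, 0)),
                       np.asarray(voxel_size, dtype=float))


def write_volume(img: VolumeImage, path, dtype=np.uint8) -> None:
    """Write a volume as a TIFF stack (page order z, y, x)."""
    info = np.iinfo(dtype)
    data = np.clip(np.rint(img.intensities), info.min, info.max).astype(dtype)
    tifffile.imwrite(path, data.transpose(2, 1, 0))


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------

def seed_from_ray(img: VolumeImage, ray: Ray) -> np.ndarray:
    """First location of maximum intensity along a view ray.

    The ray is clipped to the volume bounds (voxel centres at integer
    coordinates, faces half a voxel beyond the outermost centres) and
    sampled at half-voxel steps with nearest-voxel intensity lookup.
    Among all samples the *first* one (smallest ray parameter)
    attaining the maximum wins, and the centre of its voxel is
    returned.  Raises :class:`TraceError` when the ray misses the
    volume entirely.
    """
    lo = np.full(3, -0.5)
    hi = np.array(img.shape, dtype=float) - 0.5
    t0, t1 = 0.0, math.inf
    for ax in range(3):
        o, d = ray.origin[ax], ray.direction[ax]
        if abs(d) < 1e-300:
            if not (lo[ax] <= o <= hi[ax]):
                raise TraceError("ray misses the volume")
            continue
        ta, tb = (lo[ax] - o) / d, (hi[ax] - o) / d
        if ta > tb:
            ta, tb = tb, ta
        t0, t1 = max(t0, ta), min(t1, tb)
    if t0 > t1:
        raise TraceError("ray misses the volume")

    ts = np.arange(t0, t1 + 1e-12, 0.5)
    if ts.size == 0:
        ts = np.array([t0])
    pts = ray.origin[None, :] + ts[:, None] * ray.direction[None, :]
    idx = np.clip(np.rint(pts).astype(int), 0, np.array(img.shape) - 1)
    vals = img.intensities[idx[:, 0], idx[:, 1], idx[:, 2]]
    best = int(np.argmax(vals))  # argmax returns the first maximum
    return idx[best].astype(float)


# ---------------------------------------------------------------------------
# geodesic shortest path
# ---------------------------------------------------------------------------

def _neighbor_offsets(voxel_size: np.ndarray) -> list[tuple[tuple[int, int, int], float]]:
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                step = math.sqrt(((np.array([dx, dy, dz]) * voxel_size) ** 2).sum())
                offs.append(((dx, dy, dz), step))
    return offs


def geodesic_path(img: VolumeImage, src, dst,
                  alpha: float = DEFAULT_ALPHA) -> PathTrace:
    """Globally minimal-cost path between two voxels.

    Dijkstra over the 26-connected voxel graph with the exponential
    intensity-weighted metric described in the module docstring.
    Deterministic: the priority queue orders equal-cost voxels by
    lexicographic (flattened) voxel index, and on an exact cost tie the
    predecessor with the smaller index is kept.
    """
    src = tuple(int(v) for v in src)
    dst = tuple(int(v) for v in dst)
    for p in (src, dst):
        if not img.contains_index(p):
            raise TraceError(f"voxel {p} outside volume of shape {img.shape}")
    if alpha <= 0:
        raise TraceError("alpha must be positive")
    if src == dst:
        return PathTrace([src], 0.0)

    shape = img.shape
    nyz = shape[1] * shape[2]
    nz = shape[2]

    def flat(p):
        return p[0] * nyz + p[1] * nz + p[2]

    imax = float(img.intensities.max())
    if imax > 0:
        node_factor = np.exp(-alpha * img.intensities / (2.0 * imax)).ravel()
    else:
        node_factor = np.ones(img.intensities.size)

    offsets = [(o[0] * nyz + o[1] * nz + o[2], o, s)
               for o, s in _neighbor_offsets(img.voxel_size)]

    n_vox = img.intensities.size
    dist = np.full(n_vox, np.inf)
    pred = np.full(n_vox, -1, dtype=np.int64)
    s, d = flat(src), flat(dst)
    dist[s] = 0.0
    heap = [(0.0, s)]
    sx, sy, sz = shape
    while heap:
        du, u = heapq.heappop(heap)
        if du > dist[u]:
            continue
        if u == d:
            break
        ux, rem = divmod(u, nyz)
        uy, uz = divmod(rem, nz)
        fu = node_factor[u]
        for doff, (ox, oy, oz), step in offsets:
            vx, vy, vz = ux + ox, uy + oy, uz + oz
            if not (0 <= vx < sx and 0 <= vy < sy and 0 <= vz < sz):
                continue
            v = u + doff
            nd = du + step * fu * node_factor[v]
            if nd < dist[v]:
                dist[v] = nd
                pred[v] = u
                heapq.heappush(heap, (nd, v))
            elif nd == dist[v] and u < pred[v]:
                pred[v] = u
    if not np.isfinite(dist[d]):  # pragma: no cover - connected grid
        raise TraceError("no path found")

    path_flat = [d]
    while path_flat[-1] != s:
        path_flat.append(int(pred[path_flat[-1]]))
    path_flat.reverse()
    path = []
    for f in path_flat:
        x, rem = divmod(f, nyz)
        y, z = divmod(rem, nz)
        path.append((x, y, z))
    return PathTrace(path, float(dist[d]))


def resample_path(voxel_path, spacing: float) -> list[np.ndarray]:
    """Points at arclength multiples of ``spacing`` along a voxel polyline.

    Both endpoints are always included; a spacing longer than the whole
    path yields just the two endpoints, and a single-point path yields
    that point.
    """
    if spacing <= 0:
        raise TraceError("spacing must be positive")
    pts = [np.asarray(p, dtype=float) for p in voxel_path]
    if not pts:
        raise TraceError("cannot resample an empty path")
    if len(pts) == 1:
        return [pts[0]]
    seg = np.array([np.linalg.norm(b - a) for a, b in zip(pts, pts[1:])])
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = float(cum[-1])
    targets = list(np.arange(0.0, total - 1e-9, spacing)) + [total]
    out = []
    j = 0
    for t in targets:
        while j < len(seg) - 1 and cum[j + 1] < t:
            j += 1
        if seg[j] == 0:
            out.append(pts[j].copy())
        else:
            frac = (t - cum[j]) / seg[j]
            out.append(pts[j] + frac * (pts[j + 1] - pts[j]))
    return out


# ---------------------------------------------------------------------------
# radius estimation
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int = 64) -> np.ndarray:
    """Deterministic, roughly uniform unit directions (spiral lattice)."""
    k = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


_SHELL_DIRS = _fibonacci_sphere(64)


def estimate_radius(img: VolumeImage, point, rho_max: float = 8.0) -> float:
    """Shell-based local radius estimate at ``point``.

    Scans shell radii 0.5, 1.0, ... and keeps growing while the mean
    nearest-voxel intensity on the sphere shell stays at or above half
    the intensity at the point itself; the last passing radius is
    returned (floor 0.5).  A point sitting on zero signal returns the
    floor immediately.
    """
    point = np.asarray(point, dtype=float)
    if not img.contains_index(np.rint(point)):
        raise TraceError(f"point {tuple(point)} outside the volume")
    center_val = float(img.intensities[img.nearest_voxel(point)])
    if center_val <= 0:
        return 0.5
    shape = np.array(img.shape)
    best = 0.5
    rho = 0.5
    while rho <= rho_max:
        samples = point[None, :] + rho * _SHELL_DIRS
        idx = np.rint(samples).astype(int)
        inside = np.all((idx >= 0) & (idx < shape), axis=1)
        vals = np.zeros(len(idx))
        if inside.any():
            ii = idx[inside]
            vals[inside] = img.intensities[ii[:, 0], ii[:, 1], ii[:, 2]]
        if vals.mean() < 0.5 * center_val:
            break
        best = rho
        rho += 0.5
    return max(best, 0.5)


# ---------------------------------------------------------------------------
# point-to-point tracing into the tree
# ---------------------------------------------------------------------------

def connect_by_tracing(tree: SwcTree, img: VolumeImage, ni: int, nj: int,
                       alpha: float = DEFAULT_ALPHA,
                       spacing: float = DEFAULT_SPACING,
                       radius_mode: str = "interpolate",
                       journal: Journal | None = None) -> list[int]:
    """Connect two nodes through the image along the geodesic path.

    Traces the minimal-cost path between the voxels nearest to the two
    node centres, resamples it at ``spacing``, creates one intermediate
    node per interior sample and links the chain
    ``ni -> n'_1 -> ... -> n'_k -> nj`` (``nj``'s component is
    re-rooted at ``nj`` so the attachment is valid).  Intermediate radii
    come from ``radius_mode``: ``"interpolate"`` linearly blends
    ``r(ni)`` and ``r(nj)`` by arclength, ``"estimate"`` measures each
    radius from the image.  The nodes must lie in different connected
    components -- connecting within one component would close a loop.
    One journal entry; returns the new node ids in chain order.
    """
    a, b = tree[ni], tree[nj]
    if radius_mode not in ("interpolate", "estimate"):
        raise TraceError(f"unknown radius_mode {radius_mode!r}")
    if nj in tree.component_of(ni):
        raise TraceError(
            f"nodes {ni} and {nj} share a component: connection would loop")
    trace = geodesic_path(img, img.nearest_voxel(a.center),
                          img.nearest_voxel(b.center), alpha=alpha)
    points = resample_path(trace.voxel_path, spacing)
    seg = [float(np.linalg.norm(q - p)) for p, q in zip(points, points[1:])]
    total = sum(seg) or 1.0
    cum = np.concatenate([[0.0], np.cumsum(seg)])

    radii = []
    for k, p in enumerate(points):
        if radius_mode == "interpolate":
            frac = cum[k] / total
            radii.append(a.radius + frac * (b.radius - a.radius))
        else:
            radii.append(estimate_radius(img, p))
    trace.resampled_nodes = [(p.copy(), float(r)) for p, r in zip(points, radii)]

    new_ids: list[int] = []
    with op_transaction(tree, f"trace({ni}->{nj})", journal):
        j = journal_of(tree, journal)
        prev = ni
        for p, r in zip(points[1:-1], radii[1:-1]):
            nid = tree.next_id()
            rec = CreateNodeRecord(nid, a.type_code, tuple(p), float(r))
            rec.apply(tree)
            j.record(rec)
            set_parent(tree, nid, prev, journal)
            prev = nid
            new_ids.append(nid)
        reroot(tree, nj, journal)
        set_parent(tree, nj, prev, journal)
    return new_ids
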