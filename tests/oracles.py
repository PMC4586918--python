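"""Independent reference implementations used as test oracles.

Each function here recomputes a quantity by a route independent of the
package's own algorithms: exhaustive enumeration (spanning trees via
Pruefer sequences, injective point matchings), a library shortest-path
solver on an explicitly built sparse graph, and a from-scratch
structural consistency check used to cross-examine the validator.
"""

from __future__ import annotations

import math

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra as csgraph_dijkstra


def min_spanning_tree_weight_exhaustive(dist: np.ndarray) -> float:
    """Minimum spanning-tree weight by enumerating *all* labelled trees.

    Decodes every Pruefer sequence of length n-2 (Cayley: n^(n-2)
    labelled trees on n vertices), sums each tree's edge weights and
    returns the minimum.  Vectorised across all sequences; practical up
    to n = 8 (262144 trees).
    """
    n = dist.shape[0]
    if n == 1:
        return 0.0
    if n == 2:
        return float(dist[0, 1])
    grids = np.meshgrid(*([np.arange(n)] * (n - 2)), indexing="ij")
    seqs = np.stack([g.ravel() for g in grids], axis=1)  # (m, n-2)
    m = seqs.shape[0]
    degree = np.ones((m, n), dtype=np.int64)
    np.add.at(degree, (np.repeat(np.arange(m), n - 2), seqs.ravel()), 1)
    rows = np.arange(m)
    total = np.zeros(m)
    for i in range(n - 2):
        leaf = np.argmax(degree == 1, axis=1)  # smallest-index leaf per row
        other = seqs[:, i]
        total += dist[leaf, other]
        degree[rows, leaf] -= 1
        degree[rows, other] -= 1
    rem = degree == 1
    u = np.argmax(rem, axis=1)
    v = n - 1 - np.argmax(rem[:, ::-1], axis=1)
    total += dist[u, v]
    return float(total.min())


def lap_cost_exhaustive(test_pts: np.ndarray, gt_pts: np.ndarray,
                        td: float) -> float:
    """Minimum of ``sum d_m + td * (unmatched_test + unmatched_gt)``
    over every injective partial matching with all matched distances
    <= td.  Pure recursion; practical for <= 6 points per side."""
    test_pts = np.asarray(test_pts, dtype=float).reshape(-1, 3)
    gt_pts = np.asarray(gt_pts, dtype=float).reshape(-1, 3)
    n1, n2 = len(test_pts), len(gt_pts)
    best = math.inf

    def rec(i: int, used: frozenset, cost: float) -> None:
        nonlocal best
        if i == n1:
            best = min(best, cost + td * (n2 - len(used)))
            return
        rec(i + 1, used, cost + td)  # test point i unmatched
        for j in range(n2):
            if j in used:
                continue
            d = float(np.linalg.norm(test_pts[i] - gt_pts[j]))
            if d <= td:
                rec(i + 1, used | {j}, cost + d)

    rec(0, frozenset(), 0.0)
    return best


def geodesic_cost_oracle(intensities: np.ndarray, voxel_size, src, dst,
                         alpha: float) -> float:
    """Shortest-path cost on the 26-connected voxel graph via scipy's
    csgraph Dijkstra, with the exponential intensity-weighted metric
    built explicitly as a sparse matrix."""
    intensities = np.asarray(intensities, dtype=float)
    shape = intensities.shape
    voxel_size = np.asarray(voxel_size, dtype=float)
    imax = intensities.max()
    if imax > 0:
        factor = np.exp(-alpha * intensities / (2.0 * imax))
    else:
        factor = np.ones_like(intensities)

    idx = np.arange(intensities.size).reshape(shape)
    rows, cols, vals = [], [], []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) <= (0, 0, 0):
                    continue  # undirected: take each offset once
                step = float(np.linalg.norm(np.array([dx, dy, dz]) * voxel_size))
                sl_a = tuple(slice(max(0, -d), min(s, s - d))
                             for d, s in zip((dx, dy, dz), shape))
                sl_b = tuple(slice(max(0, d), min(s, s + d))
                             for d, s in zip((dx, dy, dz), shape))
                a, b = idx[sl_a].ravel(), idx[sl_b].ravel()
                w = step * factor.ravel()[a] * factor.ravel()[b]
                rows.append(a)
                cols.append(b)
                vals.append(w)
    graph = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(intensities.size, intensities.size))
    s = int(idx[tuple(src)])
    d = int(idx[tuple(dst)])
    cost = csgraph_dijkstra(graph, directed=False, indices=s)[d]
    return float(cost)


def independent_validity_check(tree) -> bool:
    """Structural validity recomputed from first principles.

    Uses networkx for parent-link acyclicity and re-derives the
    child/sibling chain constraints from the parent column alone.
    """
    import networkx as nx

    nodes = {n.id: n for n in tree}
    for n in nodes.values():
        for link in (n.parent, n.first_child, n.next_sibling):
            if link is not None and link not in nodes:
                return False
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from((nid, n.parent) for nid, n in nodes.items()
                     if n.parent is not None)
    if not nx.is_directed_acyclic_graph(g):
        return False
    for n in nodes.values():
        if n.next_sibling is not None and \
                nodes[n.next_sibling].parent != n.parent:
            return False
    by_parent: dict[int, set[int]] = {}
    for nid, n in nodes.items():
        if n.parent is not None:
            by_parent.setdefault(n.parent, set()).add(nid)
    for nid, n in nodes.items():
        chain = []
        cur = n.first_child
        while cur is not None:
            if cur in chain or len(chain) > len(nodes):
                return False
            chain.append(cur)
            cur = nodes[cur].next_sibling
        if set(chain) != by_parent.get(nid, set()):
            return False
        if any(nodes[c].parent != nid for c in chain):
            return False
    return True
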