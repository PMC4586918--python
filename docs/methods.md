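# Methods

## The model

An SWC reconstruction is a forest of spheres: node `n_i = (x_i, y_i,
z_i, r_i, parent)`, with a distinguished empty node `n0` that roots
hang from.  In memory every node is stored as the redundant tuple
`(G(n), P(n), C(n), S(n))` — geometry plus parent, *first child* and
*next sibling* links — so all neighbourhood queries are O(1).  The
redundancy buys speed at the price of consistency rules: `P(C(n)) = n`,
`P(S(n)) = P(n)`, sibling chains terminate and cover exactly the
children, and parent links are acyclic (at most one upstream path
between any two nodes).  `validate_tree` audits exactly these rules;
every public operation must leave them intact.

## The operation algebra

Structural edits are built in three levels.  Level 1 is the three raw
link writes `f_p`, `f_c`, `f_s`: each overwrites one link field of one
node and returns a record `(kind, node, old, new)`; validity is
deliberately *not* guaranteed here.  Level 2 composes them into the
simple valid operations:

* `detach` (`F_p0`): if `n` is its parent's first child, the parent's
  child link moves to `S(n)`, otherwise the previous sibling's link
  skips `n`; then `P(n)` and `S(n)` are cleared — exactly three
  elementary records.
* `set_parent` (`F_p`): detach, then `P(n) := n2`, `S(n) := C(n2)`,
  `C(n2) := n`, which makes `n` the **first** child of `n2`.
* `set_sibling` (`F_s`): detach the inserted node (its own subtree
  stays beneath it), then rethread it after `n` with `P = P(n)`.

Level 3 is everything composed from level 2.  Because every mutation
reduces to invertible elementary records, undo is just the reversed
sequence of inverted records and redo the forward replay; one public
operation commits one journal entry, so one undo reverts one user
action, to unbounded depth.

Two design points were genuinely open and are fixed as follows:

* **Loop guards.**  The level-2 compositions assume benign inputs; the
  public operations reject, before any mutation, a `set_parent` whose
  target is a descendant of the moved node and a `set_sibling` whose
  inserted node is an ancestor of the shared parent.  Acyclicity must
  hold after every public call.
* **Journal record kinds.**  Pure link records cannot express the
  reversal of a geometry change or of node creation/removal, so the
  journal carries three extra record kinds (`geometry`, `create_node`,
  `delete_node`).  A node is only ever removed after being fully
  detached, so its delete record is a complete snapshot.

## The editing operations

All high-level edits are single journal entries built on the algebra.
Parameter conventions that the tree format alone does not determine:

* **Interpolate** uses the index fraction `j/(k+1)` between the two
  unselected anchors, not arclength — deterministic and independent of
  the pre-edit noise being corrected.  Runs touching a terminus, a
  root, or a branch point are skipped and reported.
* **Connect multiple nodes** weights the complete selection graph by
  centre-to-centre Euclidean distance (radii ignored) and realises MST
  edges whose endpoints lie in different components; the smaller
  component is re-rooted at its endpoint and attached (`set_parent`),
  ties on size going to the larger id.  Intra-component edges are
  skipped — the loop ban wins over the spanning tree.  The MST itself
  is a hand-rolled Prim with id tie-breaks: it must treat co-located
  nodes (zero-weight edges) as ordinary edges, which sparse-matrix MST
  routines silently drop.
* **Set branch point** reads "the latest node in isolated branches" as
  the *nearest terminal node of another connected component*: temporal
  tracing order is not recoverable from a file, so nearest-terminal is
  the deterministic surrogate.  The connection is refused unless it
  creates a branch point (selected node degree >= 2 beforehand).
* **Reset branch point** walks along the segment through the selected
  node to the nearest degree->=3 node `b`, then moves the incident
  branch whose direction at `b` deviates most from a straight
  continuation of that segment (the most perpendicular one), ties by
  smallest id.  Both child branches and the upstream (parent) branch
  are candidates; moving the upstream branch detaches `b` and re-roots
  the upstream component first.
* **Remove turn** midpoints the sharpest flank pair when its angle at
  the node is acute (< 90 deg), averaging the flank radii; at a branch
  point the flanks are the sharpest pair among all neighbours.  The
  angle at the node can only grow.
* **Resolve crossover** requires a hub of degree >= 4, pairs the arms
  by exhaustively minimising total turning (sum of `180 deg - angle`
  per pair; lexicographic tie-break; odd hubs leave one arm behind),
  and rebuilds each pair as one continuous path through its own
  co-located copy of the hub.  To avoid minting a spurious branch point
  at an arm head that must accept the pass-through hub as a child, that
  arm is first re-rooted at its first child (reversing its internal
  orientation, which preserves its critical points).  For an even hub
  the node count grows by (pairs - 1).  Degree counts parent plus
  children throughout; a hub detected *near* but not exactly at a
  single node is out of scope.
* **Delete** orphans the children of removed nodes (they become roots)
  rather than bridging them to the grandparent.

## Image-dependent operations

The tracing internals are not pinned down by the editing algebra; the
package fixes simple, reproducible choices and exposes them as
parameters:

* **Geodesic cost.**  26-connected voxel graph; edge weight
  `step_length * exp(-alpha * mean(I_u, I_v) / I_max)` with
  `alpha = 5` by default; `I_max = 0` degrades to plain Euclidean
  distance.  Dijkstra with a lexicographic voxel-index tie-break makes
  the result deterministic.  Raising `alpha` never makes a bright
  route relatively more expensive.
* **Seeding.**  The view ray is clipped to the volume and sampled at
  half-voxel steps (a step that cannot skip a voxel); the first sample
  attaining the maximum intensity wins and its voxel centre is
  returned.
* **Resampling** places nodes at arclength multiples of `spacing`
  (default 3 voxels), endpoints always included.
* **Radius.**  `"interpolate"` blends the endpoint radii linearly by
  arclength; `"estimate"` grows spherical shells in half-voxel steps
  and keeps the last shell whose mean intensity is at least half the
  centre intensity (floor 0.5).  The scan stops at the first failing
  shell so a distant bright structure cannot re-qualify a larger
  radius, and a zero-intensity centre returns the floor at once — the
  unguarded "largest passing radius" rule would accept every shell
  there.
* Coordinates are voxel-index positions (voxel `(0,0,0)` centre at the
  origin, 0-based); `voxel_size` enters only through step lengths.

## The comparison metric

Critical points are branch points (>= 2 children) and termini (total
degree <= 1; a root with one child is an endpoint of the drawn
morphology and counts).  Branch points and termini are matched as two
separate assignment problems — a branch point co-located with a
terminus must not match it — each solved exactly on a cost matrix
augmented with dummy rows/columns priced at `T_d` and forbidden
real pairs beyond `T_d`, so the optimal assignment cost equals
`sum d_m + T_d (F_p + F_n)`.  The pooled error is

    Error(T_d) = (T_d (F_p + F_n) + sum d_m) / N .

`N` is not uniquely determined by the formula's description; this
package counts the critical points of **both** trees
(`N = F_p + F_n + 2M`), which makes the metric symmetric in its two
arguments — consistent with treating the two reconstructions'
mistakes equally — and keeps the convenient identities used in the
tests (uniform displacement `delta` with unchanged topology gives
exactly `delta/2`; a single displaced pair transitions from error
`T_d` to `d/2` exactly at `T_d = d`).  The one-sided conventions
remain available via `n_convention`.  Optimality, not the particular
solver, is the observable: any exact assignment solver satisfies the
contract, and the tests check it against exhaustive enumeration.

## Synthetic fixtures and what they do (not) show

`generate_random_tree` grows a branching random walk; the defaults
(40 nodes, branch probability 0.1, step 5, radii 0.5–2, 20 deg wobble)
give trees with a handful of branch points and termini spaced several
steps apart — enough separation that jittered critical points match
their true partners.  `render_tree_volume` rasterises edges as
capsules with linearly interpolated radii on a constant background
(optional Gaussian noise, clipped to [0, 255]); there is no
point-spread blur, anisotropy or autofluorescence, so passing tests
demonstrate algorithmic correctness on clean tubular signal, not
robustness to real microscopy artefacts.  `perturb_tree` emulates
tracing error modes (isotropic jitter, dropped terminal branches,
spurious short branches); with jitter-only perturbation of
`sigma = 2`, the measured error at `T_d = 20` sits within a few
percent of the analytic mean-displacement/2 (ratio ≈ 0.995 over 50
seeds — slightly below 1 because an optimal matching can only
undercut the true pairing).  All generators consume a single integer
seed and no global random state.

## Problem sizes

The stress suites run 10^4 random operations over 100 trees, 500
undo sequences, 200 instances each of the MST, assignment and
geodesic oracle comparisons (selections <= 8 nodes, point sets <= 6 a
side, volumes <= 6^3 — the sizes at which exhaustive enumeration is
exact and quick), 50 seeds for the jitter-recovery experiment and 200
round-trips; the full suite finishes in well under a minute of compute
for the acceptance properties.  The phantom-tracing check uses a
radius-3, length-50 tube in a 61 x 21 x 21 volume with 5-voxel
resampling, which places a node exactly at the tube midpoint so the
interpolated mid-radius equals the endpoint mean to machine precision.

## Known limitations

* Journals are in-memory only; histories are not persisted or merged.
* Crossover hubs must be a single degree->=4 node; geometric near-miss
  hubs are not detected.
* The radius estimator and geodesic cost are pragmatic defaults, not
  fits to any imaging model.
* Multi-tile coordinate systems, type-code semantics and non-SWC
  morphology formats are out of scope.
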