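"""High-level editing operations: geometry fixes and topology repairs."""

import math

import numpy as np
import pytest

import swcedit as s
from oracles import min_spanning_tree_weight_exhaustive


def scatter_tree(points, radius=1.0):
    """A forest of isolated single-node trees at the given points."""
    tree = s.SwcTree()
    for i, p in enumerate(points, start=1):
        tree.add(s.SwcNode(i, 3, p, radius))
    return tree


class TestGeometryEdits:
    def test_move_changes_no_links(self, y_tree):
        before = {n.id: (n.parent, n.first_child, n.next_sibling) for n in y_tree}
        s.move_node(y_tree, 2, (5.0, 5.0, 5.0))
        assert {n.id: (n.parent, n.first_child, n.next_sibling)
                for n in y_tree} == before
        assert np.allclose(y_tree[2].center, (5, 5, 5))

    def test_move_to_same_point_is_stable(self, y_tree):
        s.move_node(y_tree, 2, y_tree[2].center)
        assert np.allclose(y_tree[2].center, (1, 0, 0))

    def test_set_radius_then_undo(self, y_tree):
        s.set_radius(y_tree, 3, 2.5)
        assert y_tree[3].radius == 2.5
        s.undo(y_tree)
        assert y_tree[3].radius == 1.0

    def test_nonpositive_radius_rejected(self, y_tree):
        with pytest.raises(s.EditError):
            s.set_radius(y_tree, 3, 0.0)


class TestExtendDelete:
    def test_extend_leaf(self, chain5):
        nid = s.extend_branch(chain5, 5, (5.0, 0.0, 0.0))
        assert chain5[nid].parent == 5
        assert chain5[nid].radius == chain5[5].radius
        s.undo(chain5)
        assert nid not in chain5 and len(chain5) == 5

    def test_delete_leaf(self, y_tree):
        s.delete_nodes(y_tree, [4])
        assert y_tree.children_of(2) == [3]

    def test_delete_internal_node_orphans_downstream(self, chain5):
        s.delete_nodes(y_tree := chain5, [3])
        assert sorted(y_tree.roots()) == [1, 4]
        assert s.validate_tree(y_tree).is_valid
        s.undo(y_tree)
        assert y_tree.roots() == [1] and y_tree[4].parent == 3

    def test_delete_all_empties_tree(self, y_tree):
        s.delete_nodes(y_tree, sorted(y_tree.ids()))
        assert len(y_tree) == 0
        s.undo(y_tree)
        assert len(y_tree) == 4 and s.validate_tree(y_tree).is_valid


class TestInterpolate:
    def test_single_node_linear_formula(self, make_tree):
        tree = make_tree([(1, None, (0, 0, 0), 1.0), (2, 1, (0.3, 0.7, 0), 1.9),
                          (3, 2, (2, 0, 0), 3.0)])
        skipped = s.interpolate_nodes(tree, [2])
        assert skipped == []
        assert np.allclose(tree[2].center, (1, 0, 0))
        assert tree[2].radius == pytest.approx(2.0)

    def test_empty_selection_noop(self, chain5):
        snap = chain5.copy()
        s.interpolate_nodes(chain5, [])
        assert chain5.structurally_equal(snap)

    def test_equal_anchors_collapse(self, make_tree):
        tree = make_tree([(1, None, (1, 1, 1), 2.0), (2, 1, (9, 9, 9), 5.0),
                          (3, 2, (1, 1, 1), 2.0)])
        s.interpolate_nodes(tree, [2])
        assert np.allclose(tree[2].center, (1, 1, 1))
        assert tree[2].radius == pytest.approx(2.0)

    def test_run_of_two_fractions(self, make_tree):
        tree = make_tree([(1, None, (0, 0, 0), 1.0), (2, 1, (5, 5, 0), 1.0),
                          (3, 2, (7, 7, 0), 1.0), (4, 3, (3, 0, 0), 4.0)])
        s.interpolate_nodes(tree, [2, 3])
        assert np.allclose(tree[2].center, (1, 0, 0))
        assert np.allclose(tree[3].center, (2, 0, 0))
        assert tree[2].radius == pytest.approx(2.0)
        assert tree[3].radius == pytest.approx(3.0)

    def test_run_touching_terminus_skipped(self, chain5):
        snap = chain5.copy()
        skipped = s.interpolate_nodes(chain5, [5])
        assert skipped == [[5]]
        assert chain5.structurally_equal(snap)

    def test_branch_point_run_skipped(self, y_tree):
        skipped = s.interpolate_nodes(y_tree, [2])
        assert skipped == [[2]]

    def test_topology_never_changes(self, make_tree):
        tree = make_tree([(i, i - 1 if i > 1 else None,
                           (float(i) + 0.3 * (-1) ** i, 0.1 * i, 0), 1.0)
                          for i in range(1, 8)])
        parents = {n.id: n.parent for n in tree}
        s.interpolate_nodes(tree, [3, 4, 5])
        assert {n.id: n.parent for n in tree} == parents


class TestConnectMst:
    def test_three_collinear_points(self):
        tree = scatter_tree([(0, 0, 0), (1, 0, 0), (2, 0, 0)])
        made = s.connect_nodes_mst(tree, [1, 2, 3])
        edges = {tuple(sorted(e)) for e in made}
        assert edges == {(1, 2), (2, 3)}
        assert len(tree.components()) == 1
        assert s.validate_tree(tree).is_valid

    def test_two_nodes_single_connection(self):
        tree = scatter_tree([(0, 0, 0), (3, 4, 0)])
        made = s.connect_nodes_mst(tree, [1, 2])
        assert len(made) == 1

    def test_same_component_untouched(self, chain5):
        snap = chain5.copy()
        made = s.connect_nodes_mst(chain5, [1, 5])
        assert made == []
        assert chain5.structurally_equal(snap)

    def test_single_node_selection_rejected(self, chain5):
        with pytest.raises(s.EditError):
            s.connect_nodes_mst(chain5, [3])

    def test_undoable_in_one_step(self):
        tree = scatter_tree([(0, 0, 0), (4, 0, 0), (0, 5, 0)])
        snap = tree.copy()
        s.connect_nodes_mst(tree, [1, 2, 3])
        s.undo(tree)
        assert tree.structurally_equal(snap)

    @pytest.mark.parametrize("seed", range(30))
    def test_total_length_matches_exhaustive_minimum(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 8))
        pts = rng.uniform(0, 30, size=(n, 3))
        tree = scatter_tree(pts)
        made = s.connect_nodes_mst(tree, list(range(1, n + 1)))
        total = sum(float(np.linalg.norm(tree[a].center - tree[b].center))
                    for a, b in made)
        diff = pts[:, None, :] - pts[None, :, :]
        dist = np.sqrt((diff ** 2).sum(axis=2))
        assert total == pytest.approx(
            min_spanning_tree_weight_exhaustive(dist), abs=1e-9)


class TestSetBranchPoint:
    def fixture_segment_plus_stub(self):
        tree = s.SwcTree()
        for i, x in enumerate(range(5), start=1):
            tree.add(s.SwcNode(i, 3, (float(x), 0, 0), 1.0))
            if i > 1:
                s.set_parent(tree, i, i - 1)
        tree.add(s.SwcNode(10, 3, (2.0, 3.0, 0), 1.0))
        tree.add(s.SwcNode(11, 3, (2.0, 2.0, 0), 1.0))
        s.set_parent(tree, 11, 10)
        return tree

    def test_attaches_nearest_free_end_creating_branch(self):
        tree = self.fixture_segment_plus_stub()
        target = s.set_branch_point(tree, 3)  # mid-segment, degree 2
        assert target == 11  # the nearer terminus of the isolated stub
        assert tree[11].parent == 3
        assert tree.degree(3) == 3
        assert s.validate_tree(tree).is_valid

    def test_free_single_node_refused(self):
        tree = scatter_tree([(0, 0, 0), (1, 0, 0)])
        with pytest.raises(s.EditError):
            s.set_branch_point(tree, 1)  # degree 0 can never become >= 3

    def test_nearest_of_two_candidates_wins(self, chain5):
        chain5.add(s.SwcNode(20, 3, (2.0, 1.0, 0), 1.0))  # distance 1
        chain5.add(s.SwcNode(21, 3, (2.0, 2.0, 0), 1.0))  # distance 2
        assert s.set_branch_point(chain5, 3) == 20

    def test_no_other_component_refused(self, chain5):
        with pytest.raises(s.EditError):
            s.set_branch_point(chain5, 3)


class TestResetBranchPoint:
    def t_shape(self):
        # horizontal chain 1-2-3-4-5 with a vertical stub at node 3
        tree = s.SwcTree()
        for i, x in enumerate(range(5), start=1):
            tree.add(s.SwcNode(i, 3, (float(x), 0, 0), 1.0))
            if i > 1:
                s.set_parent(tree, i, i - 1)
        tree.add(s.SwcNode(6, 3, (2.0, 1.0, 0), 1.0))
        s.set_parent(tree, 6, 3)
        return tree

    def test_perpendicular_stub_moves_to_selected_node(self):
        tree = self.t_shape()
        moved = s.reset_branch_point(tree, 4)  # one node right of the branch
        assert moved == 6
        assert tree[6].parent == 4
        assert tree.degree(3) == 2 and tree.degree(4) == 3
        assert s.validate_tree(tree).is_valid

    def test_symmetric_branches_tie_break_smallest_id(self, make_tree):
        # two symmetric stubs: ids 6 and 7, both at 90 degrees
        tree = self.t_shape()
        tree.add(s.SwcNode(7, 3, (2.0, -1.0, 0), 1.0))
        s.set_parent(tree, 7, 3)
        assert s.reset_branch_point(tree, 4) == 6

    def test_no_adjacent_branch_point_errors(self, chain5):
        before = chain5.copy()
        with pytest.raises(s.EditError):
            s.reset_branch_point(chain5, 3)
        assert chain5.structurally_equal(before)

    def test_upstream_branch_can_move(self):
        # branch point at 3; select node 6 on the stub: through-direction
        # is the stub, the most perpendicular remaining branch moves to 6
        tree = self.t_shape()
        moved = s.reset_branch_point(tree, 6)
        assert moved in (2, 4)
        assert tree[moved].parent == 6 or tree[6].first_child == moved
        assert s.validate_tree(tree).is_valid


class TestRemoveTurn:
    def test_acute_turn_midpointed(self, make_tree):
        tree = make_tree([(1, None, (0, 0, 0), 1.0), (2, 1, (1, 0, 0), 2.0),
                          (3, 2, (0, 1, 0), 3.0)])
        assert s.remove_turn(tree, 2) is True
        assert np.allclose(tree[2].center, (0, 0.5, 0))
        assert tree[2].radius == pytest.approx(2.0)

    def test_collinear_not_a_turn(self, chain5):
        assert s.remove_turn(chain5, 3) is False
        assert np.allclose(chain5[3].center, (2, 0, 0))

    def test_branch_point_uses_sharpest_pair(self, make_tree):
        # at node 2 the neighbours are 1 (angle 180 vs 3) and leaves 3, 4;
        # the sharpest pair is (3, 4) at 60 degrees
        tree = make_tree([(1, None, (-1, 0, 0), 1.0), (2, 1, (0, 0, 0), 1.0),
                          (3, 2, (2, 1, 0), 1.0), (4, 2, (2, -1, 0), 3.0)])
        assert s.remove_turn(tree, 2) is True
        assert np.allclose(tree[2].center, (2, 0, 0))
        assert tree[2].radius == pytest.approx(2.0)

    def test_angle_never_decreases(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            pts = rng.uniform(-5, 5, size=(3, 3))
            tree = s.SwcTree()
            for i, p in enumerate(pts, start=1):
                tree.add(s.SwcNode(i, 3, p, 1.0))
            s.set_parent(tree, 2, 1)
            s.set_parent(tree, 3, 2)

            def angle():
                u = tree[1].center - tree[2].center
                v = tree[3].center - tree[2].center
                c = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
                return math.degrees(math.acos(np.clip(c, -1, 1)))

            before = angle()
            s.remove_turn(tree, 2)
            assert angle() >= before - 1e-9

    def test_fewer_than_two_neighbors_rejected(self, chain5):
        with pytest.raises(s.EditError):
            s.remove_turn(chain5, 5)


def hub_with_arms(angles_deg, arm_len=1):
    """A degree-k hub at the origin with straight arms at given angles."""
    tree = s.SwcTree()
    tree.add(s.SwcNode(1, 3, (0, 0, 0), 1.0))
    nid = 1
    for a in angles_deg:
        r = math.radians(a)
        prev = 1
        for k in range(1, arm_len + 1):
            nid += 1
            tree.add(s.SwcNode(nid, 3,
                               (k * math.cos(r), k * math.sin(r), 0), 1.0))
            s.set_parent(tree, nid, prev)
            prev = nid
    tree.journal = None
    return tree


def pairing_cost_bruteforce(tree, hub, pairs):
    hub_c = tree[hub].center

    def direction(arm):
        v = tree[arm].center - hub_c
        return v / np.linalg.norm(v)

    total = 0.0
    for a, b in pairs:
        c = float(np.clip(direction(a) @ direction(b), -1, 1))
        total += 180.0 - math.degrees(math.acos(c))
    return total


def all_pairings(items):
    items = sorted(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for i, partner in enumerate(rest):
        for sub in all_pairings(rest[:i] + rest[i + 1:]):
            yield [(first, partner)] + sub


class TestResolveCrossover:
    def test_symmetric_x_pairs_opposite_arms(self):
        tree = hub_with_arms([0, 90, 180, 270])
        res = s.resolve_crossover(tree, 1)
        assert res.pairs == [(2, 4), (3, 5)]
        assert len(res.new_node_ids) == 1
        assert len(tree) == 6
        assert s.validate_tree(tree).is_valid
        cps = s.extract_critical_points(tree)
        assert len(cps.branch_points) == 0  # both paths are now plain chains

    def test_skewed_x_minimises_total_turning(self):
        tree = hub_with_arms([0, 170, 85, 275])
        res = s.resolve_crossover(tree, 1)
        assert res.pairs == [(2, 3), (4, 5)]

    def test_degree_three_refused(self, y_tree):
        with pytest.raises(s.EditError):
            s.resolve_crossover(y_tree, 2)

    def test_node_count_grows_by_pairs_minus_one(self):
        tree = hub_with_arms([0, 60, 120, 180, 240, 300], arm_len=2)
        n_before = len(tree)
        res = s.resolve_crossover(tree, 1)
        assert len(tree) == n_before + len(res.pairs) - 1
        assert s.validate_tree(tree).is_valid

    def test_odd_hub_leaves_one_arm(self):
        tree = hub_with_arms([0, 72, 144, 216, 288])
        res = s.resolve_crossover(tree, 1)
        assert res.unpaired is not None
        assert s.validate_tree(tree).is_valid

    @pytest.mark.parametrize("seed", range(20))
    def test_pairing_matches_exhaustive_minimum(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.choice([4, 6]))
        angles = sorted(rng.uniform(0, 360, size=k))
        tree = hub_with_arms(angles)
        snapshot = tree.copy()
        res = s.resolve_crossover(tree, 1)
        arms = sorted(snapshot.children_of(1))
        best = min(pairing_cost_bruteforce(snapshot, 1, p)
                   for p in all_pairings(arms))
        assert pairing_cost_bruteforce(snapshot, 1, res.pairs) == \
            pytest.approx(best, abs=1e-9)

    def test_undo_restores_hub(self):
        tree = hub_with_arms([0, 90, 180, 270], arm_len=3)
        snap = tree.copy()
        s.resolve_crossover(tree, 1)
        s.undo(tree)
        assert tree.structurally_equal(snap)
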