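"""Sholl analysis, branch decomposition and the ten-feature profile."""

import math

import numpy as np
import pytest

from astromorph import branch_decomposition, extract_profile, sholl_curve
from astromorph.morphometry import total_process_length
from astromorph.synthetic import ARCHETYPES, simulate_skeleton

from conftest import build_skeleton, sholl_dense_oracle


class TestShollCurve:
    def test_single_straight_process(self):
        # soma at origin, process to (10.5, 0, 0) in half-um steps
        rows = [(1, 1, 0, 0, 0, 1.0, -1)]
        parent = 1
        for i, x in enumerate(np.arange(0.5, 10.6, 0.5), start=2):
            rows.append((i, 3, x, 0, 0, 0.3, parent))
            parent = i
        sk = build_skeleton(rows)
        curve = sholl_curve(sk)
        assert curve.r_max == 10
        np.testing.assert_array_equal(curve.counts, np.ones(10, dtype=int))

    def test_soma_only_skeleton_empty_curve(self):
        sk = build_skeleton([(1, 1, 0, 0, 0, 2.0, -1)])
        curve = sholl_curve(sk)
        assert curve.r_max == 0
        assert len(curve.counts) == 0
        assert curve.peak_count == 0

    def test_node_exactly_on_sphere_counted_once(self):
        # tip node exactly at distance 3: half-open rule gives one crossing
        rows = [
            (1, 1, 0, 0, 0, 1.0, -1),
            (2, 3, 1.5, 0, 0, 0.3, 1),
            (3, 3, 3.0, 0, 0, 0.3, 2),
        ]
        curve = sholl_curve(build_skeleton(rows))
        np.testing.assert_array_equal(curve.counts, [1, 1, 1])

    def test_tangential_edge_crossing_sphere_twice(self):
        # chord from (2.5, -2, 0) to (2.5, 2, 0): closest approach 2.5,
        # both endpoints beyond radius 3 -> two crossings of the r=3 sphere
        rows = [
            (1, 1, 0, 0, 0, 1.0, -1),
            (2, 3, 2.5, -2.0, 0, 0.3, 1),
            (3, 3, 2.5, 2.0, 0, 0.3, 2),
        ]
        sk = build_skeleton(rows)
        counts = sholl_curve(sk).counts
        oracle = sholl_dense_oracle(sk)
        np.testing.assert_array_equal(counts, oracle)
        # radius 3: one radial crossing plus two chord crossings
        np.testing.assert_array_equal(counts, [1, 1, 3])

    @pytest.mark.parametrize("archetype", ["simple", "medium"])
    def test_matches_dense_resampling_oracle(self, archetype):
        for seed in range(8):
            sk = simulate_skeleton(ARCHETYPES[archetype], seed=seed)
            counts = sholl_curve(sk).counts
            oracle = sholl_dense_oracle(sk)
            np.testing.assert_array_equal(counts, oracle)

    def test_step_scaling_with_uniform_scaling(self):
        """Scaling geometry by s and the Sholl step by s preserves counts."""
        sk = simulate_skeleton(ARCHETYPES["medium"], seed=2)
        base = sholl_curve(sk, step=1.0)
        sk.xyz *= 2.5
        scaled = sholl_curve(sk, step=2.5)
        np.testing.assert_array_equal(base.counts, scaled.counts)


class TestBranchDecomposition:
    def test_y_tree(self, y_tree):
        branches = branch_decomposition(y_tree)
        assert len(branches) == 3
        depths = sorted(b.depth for b in branches)
        assert depths == [0, 1, 1]
        assert {b.level for b in branches} == {1, 2}

    def test_five_armed_star(self, star5):
        branches = branch_decomposition(star5)
        assert len(branches) == 5
        assert all(b.depth == 0 for b in branches)
        assert all(math.isclose(b.length, 20.0) for b in branches)

    def test_depths_match_root_path_walk(self):
        """Branch depths equal counting >=2-child nodes on the root path."""
        for seed in range(6):
            sk = simulate_skeleton(ARCHETYPES["medium"], seed=seed)
            children = sk.children()
            is_soma = sk.type_code == 1

            def path_depth(node):
                d = 0
                p = sk.parent_index[node]
                while p >= 0:
                    if not is_soma[p] and len(children[p]) >= 2:
                        d += 1
                    p = sk.parent_index[p]
                return d

            starts = [
                c
                for i in range(sk.n_nodes)
                if is_soma[i]
                for c in children[i]
                if not is_soma[c]
            ]
            # walk to each branch start node via the decomposition contract
            branches = branch_decomposition(sk)
            depth_counts = {}
            for b in branches:
                depth_counts[b.depth] = depth_counts.get(b.depth, 0) + 1
            oracle_counts = {}
            stack = list(starts)
            while stack:
                node = stack.pop()
                d = path_depth(node)
                oracle_counts[d] = oracle_counts.get(d, 0) + 1
                kids = [c for c in children[node] if not is_soma[c]]
                while len(kids) == 1:
                    node = kids[0]
                    kids = [c for c in children[node] if not is_soma[c]]
                stack.extend(kids)
            assert depth_counts == oracle_counts


class TestProfile:
    def test_five_armed_star_profile(self, star5):
        p = extract_profile(star5)
        assert p.n_primary_branches == 5
        assert p.sholl_peak_count == 5
        assert p.ramification_index == 1.0
        assert p.n_branching_points == 0
        assert p.n_branches == 5
        assert p.soma_diameter == 4.0
        assert math.isclose(p.total_process_length, 100.0)

    def test_four_bifurcating_profile(self, four_bifurcating):
        p = extract_profile(four_bifurcating)
        assert p.n_primary_branches == 4
        assert p.sholl_peak_count == 8
        assert p.ramification_index == 2.0
        assert p.n_branching_points == 4
        assert p.n_branches == 12

    def test_soma_only_ramification_missing(self):
        sk = build_skeleton([(1, 1, 0, 0, 0, 2.0, -1)])
        p = extract_profile(sk)
        assert p.n_primary_branches == 0
        assert math.isnan(p.ramification_index)
        assert p.total_process_length == 0.0

    def test_isometry_invariance(self):
        """Rigid rotation + translation leaves every feature unchanged."""
        sk = simulate_skeleton(ARCHETYPES["medium"], seed=4)
        ref = extract_profile(sk)
        theta = 0.7
        R = np.array(
            [
                [math.cos(theta), -math.sin(theta), 0],
                [math.sin(theta), math.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        sk.xyz = sk.xyz @ R.T + np.array([5.0, -3.0, 11.0])
        moved = extract_profile(sk)
        for field in (
            "total_process_length",
            "sholl_median",
            "ramification_index",
        ):
            assert getattr(moved, field) == pytest.approx(
                getattr(ref, field), rel=1e-9
            )
        for field in (
            "n_branches",
            "n_branching_points",
            "sholl_peak_count",
            "n_primary_branches",
        ):
            assert getattr(moved, field) == getattr(ref, field)

    def test_uniform_scaling_scales_length_only(self):
        sk = simulate_skeleton(ARCHETYPES["simple"], seed=9)
        ref = extract_profile(sk, sholl_step=1.0)
        s = 3.0
        sk.xyz *= s
        scaled = extract_profile(sk, sholl_step=s)
        assert scaled.total_process_length == pytest.approx(
            s * ref.total_process_length, rel=1e-9
        )
        assert scaled.n_branches == ref.n_branches
        assert scaled.sholl_peak_count == ref.sholl_peak_count
        assert scaled.n_primary_branches == ref.n_primary_branches

    def test_adding_terminal_branch_is_monotone(self):
        """A new terminal branch never decreases branch count or length."""
        sk = simulate_skeleton(ARCHETYPES["simple"], seed=12)
        ref = extract_profile(sk)
        frame = sk.to_frame()
        tip = frame.loc[frame.index[-1]]
        new_id = int(frame["id"].max()) + 1
        rows = list(
            frame[["id", "type", "x", "y", "z", "radius", "parent_id"]]
            .itertuples(index=False, name=None)
        )
        rows.append(
            (new_id, 3, tip.x + 1.0, tip.y + 1.0, tip.z, 0.2, int(tip.id))
        )
        grown = build_skeleton(rows, "grown")
        new = extract_profile(grown)
        assert new.n_branches >= ref.n_branches
        assert new.total_process_length > ref.total_process_length
        assert total_process_length(grown) > total_process_length(sk)
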