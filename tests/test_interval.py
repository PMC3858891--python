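import numpy as np
import pytest

from aglr import PenaltyConfig, annotate, audit, parse_newick
from aglr.interval import (
    Quartet,
    bottom_up,
    correction_condition,
    correct_intervals,
    interval_gap,
    merge_intervals,
    quartet_init,
    reconstruct_interval,
)
from aglr.sankoff import dp_up, min_total_cost, reconstruct_dp
from aglr.simulate import random_leaf_instance
from aglr.trees import TreeError


class TestQuartetInit:
    def test_present_leaf(self, std_config):
        q = quartet_init(136, std_config)
        assert q.astuple() == (136, 136, 80, 0)

    def test_absent_leaf(self, std_config):
        q = quartet_init(0, std_config)
        assert not q.defined
        assert (q.z, q.x) == (0, 80)

    def test_sentinel_is_penalty_sum(self):
        q = quartet_init(0, PenaltyConfig(1, 1))
        assert q.x == 2


class TestMergeIntervals:
    def test_overlapping_intersect(self):
        assert merge_intervals((125, 141), (136, 150)) == (136, 141)

    def test_disjoint_gap(self):
        assert merge_intervals((125, 136), (141, 141)) == (136, 141)

    def test_undefined_passthrough(self):
        assert merge_intervals(None, (125, 136)) == (125, 136)
        assert merge_intervals((125, 136), None) == (125, 136)
        assert merge_intervals(None, None) is None

    def test_gap_distance(self):
        assert interval_gap((125, 136), (141, 141)) == 5
        assert interval_gap((125, 141), (136, 150)) == 0
        assert interval_gap(None, (1, 2)) == 0


class TestBottomUp:
    def test_positive_cherry(self, std_config):
        t = parse_newick("(A,B);")
        q = bottom_up(t, {"A": 125, "B": 136}, std_config)[t.root]
        assert q.astuple() == (125, 136, 100, 11)

    def test_half_present_cherry(self, std_config):
        t = parse_newick("(A,B);")
        q = bottom_up(t, {"A": 0, "B": 136}, std_config)[t.root]
        assert q.astuple() == (136, 136, 50, 30)
        assert min(q.z, q.x) == 30  # one loss

    def test_cherry_plus_outgroup_root(self, std_config):
        t = parse_newick("((A,B),C);")
        q = bottom_up(t, {"A": 125, "B": 136, "C": 141}, std_config)[t.root]
        assert q.interval == (136, 141)
        assert (q.z, q.x) == (111, 16)

    def test_absent_plus_cherry_root(self, std_config):
        t = parse_newick("(Z,(A,B));")
        q = bottom_up(t, {"Z": 0, "A": 125, "B": 136}, std_config)[t.root]
        assert q.astuple() == (125, 136, 61, 41)

    def test_multifurcation_rejected(self, std_config):
        t = parse_newick("(A,B,C);")
        with pytest.raises(TreeError, match="dp"):
            bottom_up(t, {"A": 1, "B": 2, "C": 3}, std_config)

    def test_non_manhattan_rejected(self):
        t = parse_newick("(A,B);")
        with pytest.raises(ValueError, match="Manhattan"):
            bottom_up(t, {"A": 1, "B": 2}, PenaltyConfig(50, 30, lam=2))


class TestCorrectionCondition:
    def _tree(self):
        return parse_newick("(L,R);")

    def test_true_when_gene_kept_but_child_prefers_absence(self):
        t = self._tree()
        l, r = t.children(t.root)
        quartets = {
            t.root: Quartet((125, 136), z=111, x=91),
            l: Quartet(None, z=0, x=60),  # prefers absence: X > Z
            r: Quartet((125, 136), z=61, x=41),
        }
        assert correction_condition(t.root, t, quartets)

    def test_false_when_node_prefers_absence(self):
        t = self._tree()
        l, r = t.children(t.root)
        quartets = {
            t.root: Quartet((125, 136), z=20, x=91),  # X > Z
            l: Quartet(None, z=0, x=60),
            r: Quartet((125, 136), z=61, x=41),
        }
        assert not correction_condition(t.root, t, quartets)

    def test_false_when_both_children_keep_gene(self):
        t = self._tree()
        l, r = t.children(t.root)
        quartets = {
            t.root: Quartet((125, 136), z=111, x=91),
            l: Quartet((125, 125), z=80, x=0),
            r: Quartet((125, 136), z=61, x=41),
        }
        assert not correction_condition(t.root, t, quartets)


class TestCorrectedIntervals:
    def test_no_shrink_when_all_children_keep_gene(self, std_config):
        t = parse_newick("((A,B),(C,D));")
        labels = {"A": 125, "B": 141, "C": 136, "D": 150}
        q = bottom_up(t, labels, std_config)
        corr = correct_intervals(t, q, std_config)
        for v in t.internal_nodes():
            assert corr[v] == q[v].interval

    def test_flat_region_narrower_than_merge_interval(self):
        """When a zero branch shapes a node's cost profile, the flat region
        deviates from the merge of the children's intervals, and it is the
        flat region that matches the DP profile's argmin run."""
        config = PenaltyConfig(12, 11, 1)
        t = parse_newick(
            "((((((L10,L7),L8),(L11,L3)),((L9,L6),L12)),((L5,L2),L4)),L1);"
        )
        labels = {
            "L1": 52, "L4": 50, "L2": 52, "L5": 52, "L12": 50, "L6": 0,
            "L9": 51, "L3": 54, "L11": 0, "L8": 0, "L7": 54, "L10": 0,
        }
        q = bottom_up(t, labels, config)
        corr = correct_intervals(t, q, config)
        table = dp_up(t, labels, config)
        deviating = [
            v for v in t.internal_nodes() if q[v].flat != q[v].interval
        ]
        assert deviating, "expected at least one narrowed node on this instance"
        for v in t.internal_nodes():
            if corr[v] is None:
                continue
            sig = table.pos[v]
            best = sig.min()
            run = table.values[sig == best]
            lo, hi = corr[v]
            # the corrected interval is a run of DP-optimal labels
            assert best == q[v].x
            assert set(range(lo, hi + 1)) <= {int(x) for x in run}

    def test_x_constant_on_corrected_interval(self):
        """X equals the DP conditional cost at every label inside the
        corrected interval."""
        rng = np.random.default_rng(29)
        for _ in range(30):
            tree, labels, config = random_leaf_instance(rng, max_leaves=10)
            q = bottom_up(tree, labels, config)
            corr = correct_intervals(tree, q, config)
            table = dp_up(tree, labels, config)
            for v in tree.internal_nodes():
                if corr[v] is None:
                    continue
                lo, hi = corr[v]
                lo = max(lo, table.rng.g_min)
                hi = min(hi, table.rng.g_max)
                for i in range(lo, hi + 1):
                    assert table.sigma(v, i) == q[v].x


class TestTracebackIntervals:
    def test_gain_below_root_smallest_pick(self, std_config):
        t = parse_newick("(Z,(A,B));")
        labeling, cost, _, _ = reconstruct_interval(
            t, {"Z": 0, "A": 125, "B": 136}, std_config
        )
        assert labeling[t.root] == 125
        assert cost == 41

    def test_four_leaf_root_pick(self, std_config):
        t = parse_newick("((A,B),(C,D));")
        labeling, cost, _, _ = reconstruct_interval(
            t, {"A": 125, "B": 141, "C": 136, "D": 150}, std_config
        )
        assert labeling[t.root] == 136
        assert cost == 30

    def test_all_absent_root_zero(self, std_config):
        t = parse_newick("(A,B);")
        labeling, cost, _, _ = reconstruct_interval(t, {"A": 0, "B": 0}, std_config)
        assert labeling[t.root] == 0
        assert cost == 0

    def test_root_pick_policies_share_cost(self, std_config):
        t = parse_newick("(A,B);")
        labels = {"A": 125, "B": 136}
        expected = {"smallest": 125, "largest": 136, "midpoint": 130}
        for policy, lab in expected.items():
            labeling, cost, _, _ = reconstruct_interval(t, labels, std_config, root_pick=policy)
            assert labeling[t.root] == lab
            assert cost == 11


class TestEquivalenceWithDP:
    def test_costs_and_audits_agree_on_random_binary_trees(self):
        rng = np.random.default_rng(31)
        for _ in range(60):
            tree, labels, config = random_leaf_instance(rng, max_leaves=16)
            _, dp_cost, _ = reconstruct_dp(tree, labels, config)
            labeling, iv_cost, _, _ = reconstruct_interval(tree, labels, config)
            assert iv_cost == dp_cost
            sc = annotate(tree, labeling, config)
            assert audit(sc, iv_cost)

    def test_regression_standalone_preference_is_not_contextual_drop(self):
        """A child may prefer absence in isolation while the optimum keeps its
        gene; shrinking its parent's interval then loses optimality."""
        t = parse_newick(
            "((((((L7,L4),L1),L2),L10),(((L11,L9),(L6,L3)),L5)),L8);"
        )
        labels = {
            "L8": 75, "L5": 0, "L3": 77, "L6": 76, "L9": 0, "L11": 73,
            "L10": 77, "L2": 76, "L1": 0, "L4": 78, "L7": 0,
        }
        config = PenaltyConfig(37, 25, 1)
        _, dp_cost, _ = reconstruct_dp(t, labels, config)
        labeling, iv_cost, _, _ = reconstruct_interval(t, labels, config)
        assert iv_cost == dp_cost == 108
        assert audit(annotate(t, labeling, config), iv_cost)

    def test_regression_narrowing_propagates_through_x(self):
        """A zero-branch win below must feed the corrected (flat) region into
        the parent's gap, or the root minimum is under-reported."""
        t = parse_newick(
            "((((((L10,L7),L8),(L11,L3)),((L9,L6),L12)),((L5,L2),L4)),L1);"
        )
        labels = {
            "L1": 52, "L4": 50, "L2": 52, "L5": 52, "L12": 50, "L6": 0,
            "L9": 51, "L3": 54, "L11": 0, "L8": 0, "L7": 54, "L10": 0,
        }
        config = PenaltyConfig(12, 11, 1)
        _, dp_cost, _ = reconstruct_dp(t, labels, config)
        labeling, iv_cost, _, _ = reconstruct_interval(t, labels, config)
        assert iv_cost == dp_cost == 50
        assert audit(annotate(t, labeling, config), iv_cost)

    def test_no_disjoint_region_logged_on_random_instances(self, caplog):
        import logging

        rng = np.random.default_rng(37)
        with caplog.at_level(logging.WARNING, logger="aglr.interval"):
            for _ in range(50):
                tree, labels, config = random_leaf_instance(rng, max_leaves=12)
                reconstruct_interval(tree, labels, config)
        assert not caplog.records


class TestManhattanIdentity:
    def test_between_siblings_cost_is_constant(self):
        """For l <= k <= r: |k-l| + |k-r| == r - l (and larger outside)."""
        for l in range(1, 15):
            for r in range(l, 15):
                for k in range(1, 20):
                    s = abs(k - l) + abs(k - r)
                    if l <= k <= r:
                        assert s == r - l
                    else:
                        assert s > r - l


class TestLinearity:
    def test_operation_count_scales_with_node_count(self, std_config):
        rng = np.random.default_rng(41)
        from aglr.simulate import random_tree

        for n in (8, 16, 32, 64):
            tree = random_tree(rng, n)
            labels = {name: 100 + i for i, name in enumerate(tree.leaf_names)}
            stats = {}
            bottom_up(tree, labels, std_config, stats=stats)
            # exactly one constant-work visit per node, at every size
            assert stats["ops"] == tree.n_nodes == 2 * n - 1
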