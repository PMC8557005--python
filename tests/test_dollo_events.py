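"""Dollo event mapping against worked examples and independent oracles."""

import numpy as np
import pytest

import phyloloss as pl
from _oracles import brute_force_dollo, set_dollo

from conftest import random_profile_rows


class TestGainNode:
    def test_cherry(self, toy_tree):
        assert pl.gain_node(toy_tree, [1, 1, 0, 0, 0]) == toy_tree.leaf_id("B") + 1

    def test_spanning_root(self, toy_tree):
        assert pl.gain_node(toy_tree, [1, 0, 0, 0, 1]) == toy_tree.root

    def test_internal_lca(self, toy_tree):
        # presences at A and C: deepest covering node is ((A,B),(C,D)) = id 6
        assert pl.gain_node(toy_tree, [1, 0, 1, 0, 0]) == 6

    def test_single_presence_is_the_leaf(self, toy_tree):
        assert pl.gain_node(toy_tree, [1, 0, 0, 0, 0]) == toy_tree.leaf_id("A")

    def test_all_zero_rejected(self, toy_tree):
        with pytest.raises(ValueError, match="presence"):
            pl.gain_node(toy_tree, [0, 0, 0, 0, 0])


class TestAncestralStates:
    def test_all_present(self, toy_tree):
        states = pl.ancestral_states(toy_tree, [1, 1, 1, 1, 1])
        assert states.tolist() == [1] * toy_tree.n_nodes

    def test_worked_example(self, toy_tree):
        # presences A, E: state 1 at A, (A,B), (AB,CD), E, root
        states = pl.ancestral_states(toy_tree, [1, 0, 0, 0, 1])
        assert states.tolist() == [1, 0, 1, 0, 0, 0, 1, 1, 1]

    def test_single_presence(self, toy_tree):
        states = pl.ancestral_states(toy_tree, [1, 0, 0, 0, 0])
        assert states.sum() == 1
        assert states[toy_tree.leaf_id("A")] == 1

    def test_inconsistent_gain_rejected(self, toy_tree):
        with pytest.raises(ValueError, match="inconsistent"):
            pl.ancestral_states(toy_tree, [1, 0, 0, 0, 1], gain=2)


class TestLossEvents:
    def test_single_and_continuous(self, toy_tree):
        ann = pl.annotate_row(toy_tree, [1, 0, 0, 0, 1])
        kinds = {(b.child_id, b.kind) for b in ann.losses}
        assert kinds == {(toy_tree.leaf_id("B"), "single"), (5, "continuous")}

    def test_no_losses_when_all_present(self, toy_tree):
        ann = pl.annotate_row(toy_tree, [1, 1, 1, 1, 1])
        assert ann.losses == ()

    def test_single_absent_leaf(self, toy_tree):
        ann = pl.annotate_row(toy_tree, [1, 1, 0, 1, 1])
        assert [(b.child_id, b.kind) for b in ann.losses] == [
            (toy_tree.leaf_id("C"), "single")
        ]

    def test_loss_events_from_states(self, toy_tree):
        states = pl.ancestral_states(toy_tree, [1, 0, 0, 0, 1])
        losses = pl.loss_events(toy_tree, states)
        assert {b.child_id for b in losses} == {1, 5}


SMALL_TREES = [
    "((A,B),(C,D));",
    "(((A,B),C),(D,E));",
    "(A,B,C,D);",  # polytomy at the root
    "((A,(B,C)),((D,E),(F,(G,H))));",
]


class TestOracleEquivalence:
    @pytest.mark.parametrize("newick", SMALL_TREES)
    def test_exhaustive_small_trees(self, newick):
        """Every non-zero profile on every small tree matches the
        brute-force minimal-change single-gain reconstruction."""
        tree = pl.read_newick(newick)
        n = tree.n_leaves
        for bits in range(1, 2**n):
            row = np.array([(bits >> i) & 1 for i in range(n)], dtype=np.uint8)
            gain, states, losses = brute_force_dollo(tree, row)
            ann = pl.annotate_row(tree, row)
            assert ann.gain_node == gain
            assert np.array_equal(ann.states, states)
            assert [b.child_id for b in ann.losses] == losses

    @pytest.mark.parametrize("newick", SMALL_TREES[:2])
    def test_oracles_agree_with_each_other(self, newick):
        tree = pl.read_newick(newick)
        n = tree.n_leaves
        for bits in range(1, 2**n):
            row = np.array([(bits >> i) & 1 for i in range(n)], dtype=np.uint8)
            assert brute_force_dollo(tree, row)[0] == set_dollo(tree, row)[0]
            assert brute_force_dollo(tree, row)[2] == set_dollo(tree, row)[2]

    def test_random_16_leaf_cases(self, rng):
        tree = pl.simulate_tree(16, 99)
        rows = random_profile_rows(500, 16, rng)
        for row in rows:
            gain, states, losses = set_dollo(tree, row)
            ann = pl.annotate_row(tree, row)
            assert ann.gain_node == gain
            assert np.array_equal(ann.states, states)
            assert [b.child_id for b in ann.losses] == losses


class TestInvariants:
    def test_count_conservation(self, rng):
        """#presence leaves + lost-clade leaf counts = gain-clade leaf count."""
        tree = pl.simulate_tree(24, 3)
        for row in random_profile_rows(200, 24, rng):
            ann = pl.annotate_row(tree, row)
            lost = sum(tree.clade_size(b.child_id) for b in ann.losses)
            assert int(row.sum()) + lost == tree.clade_size(ann.gain_node)

    def test_maximality_no_nested_losses(self, rng):
        tree = pl.simulate_tree(24, 4)
        for row in random_profile_rows(200, 24, rng):
            ann = pl.annotate_row(tree, row)
            children = ann.loss_children
            for b in ann.losses:
                assert ann.states[b.parent_id] == 1
                for other in children - {b.child_id}:
                    assert not tree.is_ancestor(b.child_id, other)

    def test_kind_by_child_leafness(self, rng):
        tree = pl.simulate_tree(24, 5)
        for row in random_profile_rows(100, 24, rng):
            for b in pl.annotate_row(tree, row).losses:
                assert b.kind == ("single" if tree.is_leaf(b.child_id) else "continuous")


class TestAnnotateGenome:
    def test_composition_and_skips(self, toy_tree, toy_profile, caplog):
        profile = pl.PhyloProfile(
            toy_profile.gene_ids + ("g_zero",),
            toy_profile.species_ids,
            np.vstack([toy_profile.values, np.zeros((1, 5), dtype=np.uint8)]),
        )
        anns = pl.annotate_genome(toy_tree, profile)
        assert set(anns) == set(toy_profile.gene_ids)
        assert anns["g_ref"].losses == anns["g_same"].losses

    def test_unaligned_rejected(self, toy_tree, toy_profile):
        scrambled = pl.PhyloProfile(
            toy_profile.gene_ids,
            tuple(reversed(toy_profile.species_ids)),
            toy_profile.values[:, ::-1],
        )
        with pytest.raises(ValueError, match="align"):
            pl.annotate_genome(toy_tree, scrambled)

    def test_identical_rows_identical_annotations(self, toy_tree, toy_profile):
        anns = pl.annotate_genome(toy_tree, toy_profile)
        a, b = anns["g_ref"], anns["g_same"]
        assert a.gain_node == b.gain_node
        assert a.losses == b.losses


class TestWorkBound:
    def test_node_visits_scale_linearly(self):
        """Per-gene node visits stay a fixed multiple of tree size."""
        ratios = []
        for n in (8, 32, 128, 512):
            tree = pl.simulate_tree(n, 11)
            rng = np.random.default_rng(n)
            rows = random_profile_rows(20, n, rng)
            visits = [pl.annotate_row(tree, r).node_visits for r in rows]
            ratios.append(max(visits) / tree.n_nodes)
        assert max(ratios) <= 2.0  # one counting pass + one clade pass
        assert max(ratios) / min(ratios) < 2.5
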