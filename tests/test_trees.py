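"""Tree model: parsing, canonical representation, symmetries."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from dtgraph import (
    DiscreteTimeTree,
    SpaceSpec,
    TreeError,
    canonical_key,
    canonical_representation,
    caterpillar_tree,
    cherries,
    expected_symmetries,
    parse_tree,
    permute_leaves,
    random_tree,
    symmetry_group_check,
    tree_from_canonical,
    trees_equal,
    write_tree,
)
from dtgraph.spaces import enumerate_trees

from conftest import ENUMERABLE


class TestSpaceSpec:
    def test_m_is_constrained_per_family(self):
        with pytest.raises(ValueError):
            SpaceSpec.dtt(1)
        with pytest.raises(ValueError):
            SpaceSpec(SpaceSpec.rnni().family, 2)
        assert SpaceSpec.from_name("dttu", 3).m == 3
        with pytest.raises(ValueError):
            SpaceSpec.from_name("dtt")

    def test_interval_counts(self):
        assert SpaceSpec.rnniu().n_intervals(7) == 6
        assert SpaceSpec.rnni().n_intervals(7) == 12
        assert SpaceSpec.nni().n_intervals(7) == 0


class TestParsing:
    def test_plain_caterpillar_topology(self, rnniu):
        t = parse_tree("((((((1,2),3),4),5),6),7);", rnniu)
        assert t.n == 7
        assert canonical_key(t) == (
            "1,2|1,2,3|1,2,3,4|1,2,3,4,5|1,2,3,4,5,6|1,2,3,4,5,6,7"
        )

    def test_three_leaf_tree_with_times(self, rnniu):
        t = parse_tree("((A[&time=0]:1,B[&time=0]:1)[&time=1]:1,C[&time=0]:2)[&time=2];", rnniu)
        assert canonical_key(t) == "A,B|A,B,C"

    def test_parent_younger_than_child_rejected(self, rnniu):
        bad = "((A[&time=0]:2,B[&time=0]:2)[&time=2]:-1,C[&time=0]:1)[&time=1];"
        with pytest.raises(TreeError):
            parse_tree(bad, rnniu)

    def test_duplicate_labels_rejected(self, rnniu):
        with pytest.raises(TreeError):
            parse_tree("((A,A),B);", rnniu)

    def test_nonbinary_rejected(self, rnniu):
        with pytest.raises(TreeError):
            parse_tree("((A,B,C),D);", rnniu)

    def test_tied_internal_times_rejected(self, rnniu):
        # balanced topology without times: both cherries at height 1
        with pytest.raises(TreeError):
            parse_tree("((A,B),(C,D));", rnniu)

    def test_interval_length_cap_enforced(self):
        text = "((A[&time=0]:3,B[&time=0]:3)[&time=3]:1,C[&time=0]:4)[&time=4];"
        with pytest.raises(TreeError):
            parse_tree(text, SpaceSpec.dttu(2))
        t = parse_tree(text, SpaceSpec.dttu(3))
        assert t.lengths == (3, 1)

    def test_ultrametric_requires_equal_leaf_times(self, rnniu, rnni):
        text = "((A[&time=0]:3,B[&time=1]:2)[&time=3]:1,C[&time=2]:2)[&time=4];"
        with pytest.raises(TreeError):
            parse_tree(text, rnniu)
        assert parse_tree(text, rnni).n == 3


class TestRoundTrips:
    @pytest.mark.parametrize("space,nmax", ENUMERABLE)
    def test_write_parse_identity_over_whole_spaces(self, space, nmax):
        for n in range(2, nmax + 1):
            for t in enumerate_trees(n, space):
                assert trees_equal(t, parse_tree(write_tree(t), space))

    @pytest.mark.parametrize("space,nmax", ENUMERABLE)
    def test_canonical_text_round_trip(self, space, nmax):
        for t in enumerate_trees(nmax, space):
            assert trees_equal(t, tree_from_canonical(canonical_key(t), space))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_random_tree_newick_round_trip(self, seed):
        rng = random.Random(seed)
        n = rng.randint(2, 12)
        space = rng.choice(
            [SpaceSpec.rnniu(), SpaceSpec.rnni(), SpaceSpec.nni(), SpaceSpec.dtt(3), SpaceSpec.dttu(2)]
        )
        t = random_tree(n, space, rng)
        assert trees_equal(t, parse_tree(write_tree(t), space))


class TestCanonicalRepresentation:
    def test_tip_dated_six_leaf_sequence(self, rnni):
        # clades in rank order for a tip-dated tree with three subtrees
        # (A,B), (C,(D,E)) and F joined above; leaf sampling interleaved
        seq = ["A", "C", "D", "B", "E", "AB", "DE", "CDE", "F", "ABF", "ABCDEF"]
        clades = [tuple(s) for s in seq]
        t = DiscreteTimeTree.from_clades(rnni, clades)
        rep = canonical_representation(t)
        assert rep.clades == tuple(tuple(s) for s in seq)
        assert rep.lengths is None  # unit intervals are implicit in RNNI

    def test_ultrametric_projection_of_same_shape(self, rnniu):
        seq = ["AB", "DE", "CDE", "ABF", "ABCDEF"]
        t = DiscreteTimeTree.from_clades(rnniu, [tuple(s) for s in seq])
        assert canonical_key(t) == "A,B|D,E|C,D,E|A,B,F|A,B,C,D,E,F"

    def test_single_cherry(self, rnniu):
        t = DiscreteTimeTree.from_clades(rnniu, [("A", "B")])
        assert canonical_key(t) == "A,B"

    def test_lengths_in_dtt_keys(self, dttu2):
        t = DiscreteTimeTree.from_clades(dttu2, [("A", "B"), ("A", "B", "C")], [2, 1])
        assert canonical_key(t) == "A,B:2|A,B,C:1"

    @pytest.mark.parametrize("space,nmax", ENUMERABLE)
    def test_equality_iff_same_canonical_form(self, space, nmax):
        n = min(nmax, 4)
        trees = list(enumerate_trees(n, space))
        keys = [canonical_key(t) for t in trees]
        assert len(set(keys)) == len(keys)  # enumeration has no isomorphic pair
        for i in range(0, len(trees), max(1, len(trees) // 12)):
            for j in range(0, len(trees), max(1, len(trees) // 12)):
                assert trees_equal(trees[i], trees[j]) == (keys[i] == keys[j])

    def test_nni_canonical_equality_matches_independent_rf_oracle(self, nni):
        # independent isomorphism oracle: zero rooted Robinson-Foulds
        # distance computed by dendropy on the emitted Newick strings
        import dendropy
        from dendropy.calculate import treecompare

        trees = list(enumerate_trees(4, nni))
        tns = dendropy.TaxonNamespace()
        dtrees = []
        for t in trees:
            dt = dendropy.Tree.get(
                data=write_tree(t),
                schema="newick",
                taxon_namespace=tns,
                rooting="force-rooted",
            )
            dt.encode_bipartitions()
            dtrees.append(dt)
        for i in range(len(trees)):
            for j in range(len(trees)):
                isomorphic = treecompare.symmetric_difference(dtrees[i], dtrees[j]) == 0
                assert isomorphic == (canonical_key(trees[i]) == canonical_key(trees[j]))

    def test_rank_order_distinguishes_trees(self, rnniu):
        a = DiscreteTimeTree.from_clades(rnniu, [("A", "B"), ("C", "D"), ("A", "B", "C", "D")])
        b = DiscreteTimeTree.from_clades(rnniu, [("C", "D"), ("A", "B"), ("A", "B", "C", "D")])
        assert not trees_equal(a, b)

    def test_validation_rejects_ill_ordered_sequence(self, rnniu):
        with pytest.raises(TreeError):
            DiscreteTimeTree.from_clades(rnniu, [("A", "B", "C"), ("A", "B")])


class TestPermutationsAndSymmetry:
    def test_identity_fixes(self, rnniu):
        t = caterpillar_tree(rnniu, ["A", "B", "C", "D"])
        sigma = {x: x for x in t.labels}
        assert trees_equal(t, permute_leaves(t, sigma))

    def test_cherry_transposition_fixes_ultrametric(self, rnniu):
        t = caterpillar_tree(rnniu, ["A", "B", "C", "D"])
        sigma = {"A": "B", "B": "A", "C": "C", "D": "D"}
        assert trees_equal(t, permute_leaves(t, sigma))

    def test_non_cherry_transposition_moves_tree(self, rnniu):
        t = caterpillar_tree(rnniu, ["A", "B", "C", "D"])
        sigma = {"A": "C", "C": "A", "B": "B", "D": "D"}
        assert not trees_equal(t, permute_leaves(t, sigma))

    def test_non_bijection_rejected(self, rnniu):
        t = caterpillar_tree(rnniu, ["A", "B", "C"])
        with pytest.raises(TreeError):
            permute_leaves(t, {"A": "B", "B": "B", "C": "C"})

    def test_three_leaf_symmetries(self, rnniu):
        t = DiscreteTimeTree.from_clades(rnniu, [("A", "B"), ("A", "B", "C")])
        assert symmetry_group_check(t) == {("A", "B", "C"), ("B", "A", "C")}

    def test_balanced_ranked_tree_symmetries(self, rnniu):
        t = DiscreteTimeTree.from_clades(rnniu, [("A", "B"), ("C", "D"), ("A", "B", "C", "D")])
        got = symmetry_group_check(t)
        # each cherry swaps independently; the crossing swap breaks ranks
        assert ("B", "A", "C", "D") in got
        assert ("A", "B", "D", "C") in got
        assert ("B", "A", "D", "C") in got
        assert ("C", "D", "A", "B") not in got
        assert got == expected_symmetries(t)

    def test_alternating_caterpillar_brute_force(self, rnniu):
        rng = random.Random(11)
        t = random_tree(5, rnniu, rng)
        assert symmetry_group_check(t) == expected_symmetries(t)

    def test_tip_dated_trees_have_no_symmetry(self, rnni):
        t = caterpillar_tree(rnni, ["A", "B", "C", "D"])
        assert cherries(t) == (("A", "B"),)
        assert symmetry_group_check(t) == {("A", "B", "C", "D")}
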