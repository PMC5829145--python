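"""Move generation, application and the degree envelope."""

import pytest

from dtgraph import (
    DiscreteTimeTree,
    InapplicableMoveError,
    Move,
    MoveKind,
    SpaceSpec,
    applicable_moves,
    apply_move,
    caterpillar_tree,
    degree,
    degree_bounds,
    is_adjacent,
    neighbors,
    trees_equal,
)
from dtgraph.moves import format_move_log, parse_move_log, replay_moves
from dtgraph.trees import alternating_caterpillar, low_degree_tree, max_length_tree
from dtgraph.spaces import enumerate_trees

from conftest import ENUMERABLE


class TestApplicableMoves:
    def test_root_interval_always_offers_both_nni_variants(self, rnniu):
        for n in (3, 4, 5):
            for t in enumerate_trees(n, SpaceSpec.rnniu()):
                root_interval = n - 2  # between ranks n-2 and n-1
                kinds = {m.kind for m in applicable_moves(t) if m.interval == root_interval}
                assert {MoveKind.NNI_A, MoveKind.NNI_B} <= kinds

    def test_all_long_intervals_leave_only_length_decreases(self, dtt2):
        t = max_length_tree(dtt2, ["a", "b", "c", "d"])
        moves = applicable_moves(t)
        assert all(m.kind is MoveKind.LENGTH_DEC for m in moves)
        assert len(moves) == 2 * 4 - 2  # one per event interval

    def test_leaf_bounded_edge_interval_admits_nothing(self, rnni):
        # taxon directly below its own parent: no NNI (leaf endpoint), no
        # rank swap (edge-connected)
        t = alternating_caterpillar(rnni, ["a", "b", "c"])
        # ranks: a=0, b=1, ab=2, c=3, abc=4; interval 3 joins c to its parent
        moves_on_3 = [m for m in applicable_moves(t) if m.interval == 3]
        assert moves_on_3 == []

    def test_nni_family_move_count(self, nni):
        for t in enumerate_trees(5, SpaceSpec.nni()):
            assert len(applicable_moves(t)) == 2 * (5 - 2)


class TestApplyMove:
    def test_rank_swap_is_involutive(self, rnniu):
        t = low_degree_tree(rnniu, ["a", "b", "c", "d"])
        mv = next(m for m in applicable_moves(t) if m.kind is MoveKind.RANK_SWAP)
        back = apply_move(apply_move(t, mv), mv)
        assert trees_equal(t, back)

    def test_three_leaf_nni_reaches_the_other_two_trees(self, rnniu):
        t = DiscreteTimeTree.from_clades(rnniu, [("A", "B"), ("A", "B", "C")])
        results = {
            apply_move(t, Move(MoveKind.NNI_A, 1)).clades,
            apply_move(t, Move(MoveKind.NNI_B, 1)).clades,
        }
        others = {
            u.clades for u in enumerate_trees(3, rnniu, labels=["A", "B", "C"])
        } - {t.clades}
        assert results == others

    def test_length_moves_cancel(self, dttu2):
        t = DiscreteTimeTree.from_clades(dttu2, [("A", "B")], [1])
        up = apply_move(t, Move(MoveKind.LENGTH_INC, 0))
        assert up.lengths == (2,)
        assert trees_equal(t, apply_move(up, Move(MoveKind.LENGTH_DEC, 0)))

    def test_inapplicable_moves_raise(self, rnniu, dttu2):
        t = caterpillar_tree(rnniu, ["A", "B", "C"])
        with pytest.raises(InapplicableMoveError):
            apply_move(t, Move(MoveKind.RANK_SWAP, 1))  # edge-connected pair
        with pytest.raises(InapplicableMoveError):
            apply_move(t, Move(MoveKind.LENGTH_INC, 0))  # not a DtT space
        d = DiscreteTimeTree.from_clades(dttu2, [("A", "B")], [2])
        with pytest.raises(InapplicableMoveError):
            apply_move(d, Move(MoveKind.LENGTH_INC, 0))  # already at m

    def test_every_move_is_reversible(self):
        for space, nmax in ENUMERABLE:
            n = min(nmax, 4)
            for t in enumerate_trees(n, space):
                for mv in applicable_moves(t):
                    u = apply_move(t, mv)
                    assert any(
                        trees_equal(t, apply_move(u, back))
                        for back in applicable_moves(u)
                    )


class TestNeighbors:
    @pytest.mark.parametrize("space,nmax", ENUMERABLE)
    def test_symmetric_deduplicated_and_move_counted(self, space, nmax):
        n = min(nmax, 4)
        for t in enumerate_trees(n, space):
            nbrs = neighbors(t)
            keys = {(u.clades, u.lengths) for u in nbrs}
            assert len(keys) == len(nbrs) == len(applicable_moves(t)) == degree(t)
            assert (t.clades, t.lengths) not in keys
            for u in nbrs:
                assert any(trees_equal(t, v) for v in neighbors(u))

    def test_three_leaf_rnniu_triangle(self, rnniu):
        t = DiscreteTimeTree.from_clades(rnniu, [("A", "B"), ("A", "B", "C")])
        assert len(neighbors(t)) == 2

    def test_two_leaf_cherry_single_length_neighbor(self, dttu2):
        t = DiscreteTimeTree.from_clades(dttu2, [("A", "B")], [1])
        nbrs = neighbors(t)
        assert len(nbrs) == 1 and nbrs[0].lengths == (2,)

    @pytest.mark.parametrize("space,nmax", ENUMERABLE)
    def test_is_adjacent_agrees_with_neighbors(self, space, nmax):
        n = min(nmax, 4)
        trees = list(enumerate_trees(n, space))
        for t in trees:
            nbr_keys = {(u.clades, u.lengths) for u in neighbors(t)}
            for u in trees:
                expected = (u.clades, u.lengths) in nbr_keys
                assert is_adjacent(t, u) == expected


class TestDegreeBounds:
    def test_printed_values(self):
        assert degree_bounds(4, SpaceSpec.nni()) == (4, 4)
        assert degree_bounds(5, SpaceSpec.dttu(2)) == (4, 10)
        assert degree_bounds(4, SpaceSpec.rnni()) == (3, 8)
        assert degree_bounds(4, SpaceSpec.dtt(2)) == (6, 14)
        with pytest.raises(ValueError):
            degree_bounds(2, SpaceSpec.rnniu())

    def test_named_extremal_trees(self, rnniu, rnni, dttu2):
        labels = ["a", "b", "c", "d", "e"]
        assert degree(caterpillar_tree(rnniu, labels)) == 2 * (5 - 2)
        assert degree(low_degree_tree(rnniu, labels)) == 5 - 1
        assert degree(alternating_caterpillar(rnni, labels)) == 5 - 1
        assert degree(caterpillar_tree(rnni, labels)) == 3 * 5 - 4
        assert degree(max_length_tree(dttu2, labels)) == 5 - 1

    @pytest.mark.parametrize("space,nmax", ENUMERABLE)
    def test_enumerated_degrees_stay_in_envelope(self, space, nmax):
        for n in range(3, nmax + 1):
            lo, hi = degree_bounds(n, space)
            degs = [degree(t) for t in enumerate_trees(n, space)]
            assert lo <= min(degs) and max(degs) <= hi


class TestMoveLog:
    def test_round_trip_and_replay(self, rnniu):
        t = caterpillar_tree(rnniu, ["a", "b", "c", "d"])
        moves = [Move(MoveKind.NNI_A, 1), Move(MoveKind.NNI_B, 2)]
        text = format_move_log(moves)
        assert parse_move_log(text) == moves
        walk = replay_moves(t, moves)
        assert len(walk) == 3
        assert all(is_adjacent(a, b) for a, b in zip(walk, walk[1:]))
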