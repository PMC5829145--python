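"""Graph construction, counts, distances and printed bounds."""

import math

import pytest

from dtgraph import (
    DiscreteTimeTree,
    SpaceSpec,
    TreeGraph,
    bfs_distance,
    build_graph,
    canonical_key,
    caterpillar_tree,
    count_trees,
    degree,
    degree_bounds,
    diameter,
    diameter_lower_bound,
    enumerate_trees,
    neighborhood_size,
    rneighborhood_bound,
    trees_equal,
)
from dtgraph.spaces import SizeGuardError
from dtgraph.examples import caterpillar_shift_pair, synthetic_dtt2_pair

from conftest import ENUMERABLE


class TestCounts:
    def test_printed_small_counts(self):
        assert [count_trees(n, SpaceSpec.rnniu()) for n in (3, 4, 5)] == [3, 18, 180]
        assert count_trees(4, SpaceSpec.nni()) == 15
        assert count_trees(4, SpaceSpec.dttu(2)) == 18 * 2**3
        assert count_trees(2, SpaceSpec.rnniu()) == 1

    @pytest.mark.parametrize("space,nmax", ENUMERABLE)
    def test_closed_forms_match_enumeration(self, space, nmax):
        for n in range(2, nmax + 1):
            assert count_trees(n, space) == sum(1 for _ in enumerate_trees(n, space))

    def test_dtt_counts_factorise_over_lengths(self):
        for n in (3, 4):
            assert count_trees(n, SpaceSpec.dtt(3)) == count_trees(
                n, SpaceSpec.rnni()
            ) * 3 ** (2 * n - 2)

    def test_enumeration_guard(self):
        with pytest.raises(SizeGuardError):
            list(enumerate_trees(9, SpaceSpec.rnni(), max_vertices=1000))


class TestBuildGraph:
    def test_rnniu_triangle(self, rnniu):
        g = build_graph(3, rnniu)
        assert (g.vertex_count, g.edge_count) == (3, 3)
        assert g.degrees() == [2, 2, 2]

    def test_two_leaves_single_vertex(self, rnniu):
        g = build_graph(2, rnniu)
        assert (g.vertex_count, g.edge_count) == (1, 0)

    @pytest.mark.parametrize("space,nmax", ENUMERABLE)
    def test_vertex_count_connectivity_and_degree_envelope(self, space, nmax):
        for n in range(3, nmax + 1):
            g = build_graph(n, space)
            assert g.vertex_count == count_trees(n, space)
            assert g.is_connected()
            lo, hi = degree_bounds(n, space)
            degs = g.degrees()
            assert lo <= min(degs) and max(degs) <= hi

    def test_vertices_sorted_by_canonical_key(self, rnniu):
        g = build_graph(4, rnniu)
        assert list(g.keys) == sorted(g.keys)

    def test_edge_tsv_round_trip(self, rnniu):
        g = build_graph(4, rnniu)
        back = TreeGraph.read_edge_tsv(g.write_edge_tsv(), rnniu)
        assert back.keys == g.keys
        assert back.adj == g.adj

    def test_dot_output_lists_all_edges(self, rnniu):
        g = build_graph(3, rnniu)
        dot = g.write_dot()
        assert dot.count(" -- ") == g.edge_count
        assert dot.startswith("graph")


class TestBfsDistance:
    def test_zero_iff_equal(self, rnniu):
        t = caterpillar_tree(rnniu, ["a", "b", "c", "d"])
        assert bfs_distance(t, t) == 0

    def test_matches_graph_distances_exhaustively(self, rnniu):
        g = build_graph(4, rnniu)
        dist = g.all_distances()
        for i in range(g.vertex_count):
            for j in range(i + 1, g.vertex_count):
                assert bfs_distance(g.trees[i], g.trees[j]) == dist[i, j]
                assert bfs_distance(g.trees[j], g.trees[i]) == dist[i, j]

    def test_synthetic_dtt2_pair_is_three_apart(self):
        t, r = synthetic_dtt2_pair()
        assert bfs_distance(t, r) == 3

    def test_caterpillar_pair_rnniu_vs_nni(self):
        t, r = caterpillar_shift_pair()
        assert bfs_distance(t, r) == 6
        nni = SpaceSpec.nni()
        tn = DiscreteTimeTree.from_clades(nni, [c for c in map(tuple, _clades(t))])
        rn = DiscreteTimeTree.from_clades(nni, [c for c in map(tuple, _clades(r))])
        assert bfs_distance(tn, rn) == 5  # grouping 2,3 into a cherry pays off

    def test_guard_raises(self, rnniu):
        t = caterpillar_tree(rnniu, [str(i) for i in range(1, 9)])
        r = caterpillar_tree(rnniu, [str(i) for i in range(8, 0, -1)])
        with pytest.raises(SizeGuardError):
            bfs_distance(t, r, max_explored=10)


def _clades(tree):
    from dtgraph import canonical_representation

    return canonical_representation(tree).clades


class TestDiameter:
    def test_triangle(self, rnniu):
        assert diameter(build_graph(3, rnniu)) == 1

    def test_single_vertex(self, rnniu):
        assert diameter(build_graph(2, rnniu)) == 0

    def test_disconnected_graph_reported(self, rnniu):
        g = build_graph(3, rnniu)
        broken = TreeGraph(g.space, g.n, g.keys, g.trees, ((), (2,), (1,)))
        with pytest.raises(ValueError, match="disconnected"):
            diameter(broken)

    def test_rnniu_sandwich_small(self, rnniu):
        for n in (4, 5):
            g = build_graph(n, rnniu)
            d = diameter(g)
            assert diameter_lower_bound(n, rnniu) <= d <= n * n - 3 * n - 5 / 8


class TestNeighborhoods:
    def test_radius_zero_and_one(self, rnniu):
        t = caterpillar_tree(rnniu, ["a", "b", "c", "d", "e"])
        assert neighborhood_size(t, 0) == 1
        assert neighborhood_size(t, 1) == 1 + degree(t)

    def test_ball_growth_capped_by_printed_bound(self, rnniu, rnni):
        t = caterpillar_tree(rnniu, ["1", "2", "3", "4"])
        for r in range(3):
            assert neighborhood_size(t, r) <= rneighborhood_bound(4, r, rnniu)
        s = caterpillar_tree(rnni, ["1", "2", "3", "4"])
        for r in range(3):
            assert neighborhood_size(s, r) <= rneighborhood_bound(4, r, rnni)

    def test_bound_values_and_monotonicity(self, rnniu):
        assert rneighborhood_bound(4, 0, SpaceSpec.rnniu()) == 3**3
        assert rneighborhood_bound(4, 1, SpaceSpec.dttu(2)) == 4**5
        assert rneighborhood_bound(4, 1, SpaceSpec.rnni()) == 3**9
        for n in (4, 5):
            for r in (0, 1, 2):
                assert rneighborhood_bound(n, r, SpaceSpec.rnniu()) < rneighborhood_bound(
                    n + 1, r, SpaceSpec.rnniu()
                )
                assert rneighborhood_bound(n, r, SpaceSpec.rnniu()) < rneighborhood_bound(
                    n, r + 1, SpaceSpec.rnniu()
                )

    def test_nni_bound_refused(self):
        with pytest.raises(ValueError):
            rneighborhood_bound(5, 1, SpaceSpec.nni())
        with pytest.raises(ValueError):
            diameter_lower_bound(5, SpaceSpec.nni())


class TestDiameterLowerBound:
    def test_printed_rnniu_instance(self):
        n = 6
        expected = 0.5 * math.log(
            math.factorial(5) * math.factorial(6) / 6**5, 3
        )
        assert diameter_lower_bound(n, SpaceSpec.rnniu()) == pytest.approx(expected)

    def test_clamped_at_zero(self):
        assert diameter_lower_bound(2, SpaceSpec.rnniu()) == 0.0
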