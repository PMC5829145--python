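"""Small reference trees used in tests, docs and the acceptance script."""

from __future__ import annotations

from .space import SpaceSpec
from .trees import DiscreteTimeTree, parse_tree

__all__ = ["caterpillar_shift_pair", "synthetic_dtt2_pair"]


def caterpillar_shift_pair() -> tuple[DiscreteTimeTree, DiscreteTimeTree]:
    """Two 7-leaf ultrametric caterpillars two leaves apart in the ladder.

    The second tree moves leaves 2 and 3 from the bottom of the ladder to
    just under the outermost leaf.  A shortest ranked (RNNIu) path can
    move the parents of 2 and 3 up independently, staying inside the
    caterpillar set the whole way, whereas a shortest plain-NNI path
    profits from first grouping 2 and 3 into a cherry and leaves the set.
    """
    space = SpaceSpec.rnniu()
    t = parse_tree("((((((1,2),3),4),5),6),7);", space)
    r = parse_tree("((((((1,4),5),6),2),3),7);", space)
    return t, r


def synthetic_dtt2_pair() -> tuple[DiscreteTimeTree, DiscreteTimeTree]:
    """Synthetic pair of 4-leaf discrete time-trees at DtT_2 distance 3.

    Constructed (not taken from any dataset) so that moving between them
    requires one of each move type, on three pairwise disjoint intervals:
    shorten the bottom interval under taxon b, swap the ranks of taxa c
    and d (they are not joined by an edge), and resolve the cherry (c,d)
    across the root interval by an NNI move.  No pair of these edits can
    be merged into one, so the trees sit at distance exactly 3 -- which
    the test suite and the acceptance script confirm by bidirectional BFS.
    """
    space = SpaceSpec.dtt(2)
    t = DiscreteTimeTree.from_clades(
        space,
        [("a",), ("b",), ("a", "b"), ("c",), ("d",), ("c", "d"), ("a", "b", "c", "d")],
        lengths=[2, 1, 1, 1, 1, 1],
    )
    r = DiscreteTimeTree.from_clades(
        space,
        [("a",), ("b",), ("a", "b"), ("d",), ("c",), ("a", "b", "c"), ("a", "b", "c", "d")],
        lengths=[1, 1, 1, 1, 1, 1],
    )
    return t, r
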