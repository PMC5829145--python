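"""Moves and adjacency for discrete time-tree graphs.

Three primitive operations connect trees:

* a **length move** changes one event-interval length by 1 (DtT families);
* a **rank swap** exchanges the ranks of the two nodes bounding a unit
  interval when they are *not* joined by a tree edge;
* an **NNI move** acts on a unit interval whose endpoints are joined by an
  edge and neither endpoint is a leaf: the interval is contracted and the
  multifurcation resolved to either of the two other trees, the new
  interval again of unit length.

In the rank-free NNI family the same NNI mechanics apply per internal
edge, giving the classical 2(n-2)-regular NNI graph.

Event intervals are indexed by the rank of their lower endpoint; indices
are recomputed after every move (no persistent interval identity).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

from .space import Family, SpaceSpec
from .trees import DiscreteTimeTree, TreeError

__all__ = [
    "MoveKind",
    "Move",
    "InapplicableMoveError",
    "applicable_moves",
    "apply_move",
    "neighbors",
    "degree",
    "degree_bounds",
    "is_adjacent",
    "format_move_log",
    "parse_move_log",
]


class MoveKind(enum.Enum):
    NNI_A = "nni_a"
    NNI_B = "nni_b"
    RANK_SWAP = "rank_swap"
    LENGTH_INC = "length_inc"
    LENGTH_DEC = "length_dec"


@dataclass(frozen=True)
class Move:
    """One edit, addressed by event-interval index (lower endpoint rank).

    For the rank-free NNI family ``interval`` is instead the canonical
    sequence position of the internal node whose parent edge is resolved.
    ``NNI_A`` displaces the lower node's child subtree containing its
    smallest taxon; ``NNI_B`` displaces the other child.
    """

    kind: MoveKind
    interval: int


class InapplicableMoveError(TreeError):
    pass


# ---------------------------------------------------------------------------
# interval geometry helpers
# ---------------------------------------------------------------------------


def _endpoints(tree: DiscreteTimeTree, interval: int) -> tuple[int | None, int | None]:
    """Sequence positions (lower, upper) of the nodes bounding an interval.

    Ultrametric interval 0 has the leaf level as its lower endpoint, which
    is not a node: lower is None there.
    """
    if tree.space.is_ultrametric:
        lower = interval - 1 if interval >= 1 else None
        upper = interval
    else:
        lower, upper = interval, interval + 1
    return lower, upper


def _nni_results(tree: DiscreteTimeTree, lower_pos: int, upper_mask: int) -> tuple[int, int]:
    """New lower-clade masks (variant A, variant B) for an NNI move."""
    u = tree.clades[lower_pos]
    w = upper_mask & ~u
    kids = tree.children_masks(lower_pos)
    # kids[0] contains the smallest taxon of u; variant A displaces it
    return kids[1] | w, kids[0] | w


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------


def applicable_moves(tree: DiscreteTimeTree, space: SpaceSpec | None = None) -> list[Move]:
    """Complete, duplicate-free list of moves applicable to ``tree``."""
    if space is not None and space != tree.space:
        raise TreeError(f"tree lives in {tree.space}, not {space}")
    space = tree.space
    moves: list[Move] = []

    if space.family is Family.NNI:
        root = tree.full_mask
        for p, c in enumerate(tree.clades):
            if c != root:  # non-root internal node: edge to parent is internal
                moves.append(Move(MoveKind.NNI_A, p))
                moves.append(Move(MoveKind.NNI_B, p))
        return moves

    m = space.m
    for i, length in enumerate(tree.lengths):
        if space.has_lengths:
            if length < m:
                moves.append(Move(MoveKind.LENGTH_INC, i))
            if length > 1:
                moves.append(Move(MoveKind.LENGTH_DEC, i))
        if length != 1:
            continue
        lower, upper = _endpoints(tree, i)
        if lower is None:
            continue  # leaf level below the most recent divergence
        lo, up = tree.clades[lower], tree.clades[upper]
        if lo & up == lo:  # connected by an edge (upper is lower's parent)
            if lo.bit_count() >= 2:
                moves.append(Move(MoveKind.NNI_A, i))
                moves.append(Move(MoveKind.NNI_B, i))
        else:
            moves.append(Move(MoveKind.RANK_SWAP, i))
    return moves


def apply_move(
    tree: DiscreteTimeTree, move: Move, space: SpaceSpec | None = None
) -> DiscreteTimeTree:
    """Apply one move, returning a new validated-by-construction tree."""
    if space is not None and space != tree.space:
        raise TreeError(f"tree lives in {tree.space}, not {space}")
    space = tree.space
    kind, i = move.kind, move.interval

    if space.family is Family.NNI:
        if kind not in (MoveKind.NNI_A, MoveKind.NNI_B):
            raise InapplicableMoveError(f"{kind.value} is undefined in the NNI graph")
        if not 0 <= i < len(tree.clades) or tree.clades[i] == tree.full_mask:
            raise InapplicableMoveError("no internal parent edge at this position")
        parent = tree.parent_pos(i)
        a, b = _nni_results(tree, i, tree.clades[parent])
        new = a if kind is MoveKind.NNI_A else b
        clades = list(tree.clades)
        clades[i] = new
        clades.sort(key=lambda msk: (msk.bit_count(), msk))
        return DiscreteTimeTree(tree.labels, tuple(clades), (), space)

    if not 0 <= i < len(tree.lengths):
        raise InapplicableMoveError(f"no event interval {i}")

    if kind in (MoveKind.LENGTH_INC, MoveKind.LENGTH_DEC):
        if not space.has_lengths:
            raise InapplicableMoveError("length moves need a DtT/DtTu space")
        delta = 1 if kind is MoveKind.LENGTH_INC else -1
        new_len = tree.lengths[i] + delta
        if not 1 <= new_len <= space.m:
            raise InapplicableMoveError(f"interval {i} length would leave [1, {space.m}]")
        lengths = list(tree.lengths)
        lengths[i] = new_len
        return DiscreteTimeTree(tree.labels, tree.clades, tuple(lengths), space)

    if tree.lengths[i] != 1:
        raise InapplicableMoveError(f"interval {i} is not of unit length")
    lower, upper = _endpoints(tree, i)
    if lower is None:
        raise InapplicableMoveError("no moves on the leaf-level interval")
    lo, up = tree.clades[lower], tree.clades[upper]
    connected = lo & up == lo

    if kind is MoveKind.RANK_SWAP:
        if connected:
            raise InapplicableMoveError("endpoints joined by an edge: rank swap illegal")
        clades = list(tree.clades)
        clades[lower], clades[upper] = clades[upper], clades[lower]
        return DiscreteTimeTree(tree.labels, tuple(clades), tree.lengths, space)

    # NNI variants
    if not connected:
        raise InapplicableMoveError("endpoints not joined by an edge: NNI illegal")
    if lo.bit_count() < 2:
        raise InapplicableMoveError("NNI moves need both endpoints internal")
    a, b = _nni_results(tree, lower, up)
    new = a if kind is MoveKind.NNI_A else b
    clades = list(tree.clades)
    clades[lower] = new
    return DiscreteTimeTree(tree.labels, tuple(clades), tree.lengths, space)


def neighbors(tree: DiscreteTimeTree, space: SpaceSpec | None = None) -> list[DiscreteTimeTree]:
    """All trees adjacent to ``tree``, deduplicated, excluding ``tree``."""
    seen: dict = {}
    for mv in applicable_moves(tree, space):
        t = apply_move(tree, mv)
        seen[(t.clades, t.lengths)] = t
    seen.pop((tree.clades, tree.lengths), None)
    return list(seen.values())


def degree(tree: DiscreteTimeTree, space: SpaceSpec | None = None) -> int:
    """Number of adjacent trees.

    Distinct applicable moves always produce distinct trees (the three
    move types edit disjoint coordinates of the clade sequence), so the
    degree equals the move count; tests cross-check this against
    ``len(neighbors(tree))`` exhaustively at small n.
    """
    return len(applicable_moves(tree, space))


def degree_bounds(n: int, space: SpaceSpec) -> tuple[int, int]:
    """(min degree, max degree) over all trees on n leaves of the space.

    NNI is 2(n-2)-regular.  Ranked-family minima are n-1 (alternating
    caterpillar in RNNI; two-branch trees in RNNIu); DtT/DtTu minima equal
    the interval count (all intervals at maximal length m).  Maxima stack
    length moves, 2 NNI moves per eligible interval and rank swaps of a
    short-interval caterpillar.  All bounds are attained.
    """
    if n < 3:
        raise ValueError("degree bounds need n >= 3")
    family = space.family
    if family is Family.NNI:
        d = 2 * (n - 2)
        return d, d
    if family is Family.RNNI:
        return n - 1, 3 * n - 4
    if family is Family.RNNIU:
        return n - 1, 2 * (n - 2)
    if family is Family.DTT:
        return 2 * n - 2, 5 * n - 6
    if family is Family.DTTU:
        return n - 1, 3 * n - 5
    raise ValueError(f"unknown family {family}")


# ---------------------------------------------------------------------------
# fast adjacency predicate
# ---------------------------------------------------------------------------


def _interval_between(tree: DiscreteTimeTree, pos: int) -> int:
    """Event-interval index between sequence positions pos and pos+1."""
    return pos + 1 if tree.space.is_ultrametric else pos


def is_adjacent(t1: DiscreteTimeTree, t2: DiscreteTimeTree) -> bool:
    """True iff the two (valid) trees are joined by a single move.

    Structural O(n) check on the clade sequences; validated against
    ``neighbors`` by exhaustive small-n tests.
    """
    if t1.labels != t2.labels:
        raise TreeError("trees are on different label sets")
    if t1.space != t2.space:
        raise TreeError(f"trees live in different spaces: {t1.space} vs {t2.space}")

    if t1.space.family is Family.NNI:
        only1 = set(t1.clades) - set(t2.clades)
        only2 = set(t2.clades) - set(t1.clades)
        if len(only1) != 1 or len(only2) != 1:
            return False
        a, b = only1.pop(), only2.pop()
        # parent of a in t1: smallest clade of t1 strictly containing a
        parents = [c for c in t1.clades if c & a == a and c != a]
        if not parents:
            return False
        p = min(parents, key=lambda c: c.bit_count())
        return (a | b) == p and a & b != 0 and a & b != a

    if t1.clades == t2.clades:
        diffs = [i for i, (x, y) in enumerate(zip(t1.lengths, t2.lengths)) if x != y]
        return len(diffs) == 1 and abs(t1.lengths[diffs[0]] - t2.lengths[diffs[0]]) == 1

    if t1.lengths != t2.lengths:
        return False
    diffs = [i for i, (x, y) in enumerate(zip(t1.clades, t2.clades)) if x != y]
    if len(diffs) == 1:
        # NNI: one clade replaced, its parent (next position) unchanged
        i = diffs[0]
        if i + 1 >= len(t1.clades):
            return False
        a, b, c = t1.clades[i], t2.clades[i], t1.clades[i + 1]
        return (a | b) == c and t1.lengths[_interval_between(t1, i)] == 1
    if len(diffs) == 2 and diffs[1] == diffs[0] + 1:
        i = diffs[0]
        if t1.clades[i] != t2.clades[i + 1] or t1.clades[i + 1] != t2.clades[i]:
            return False
        lo, up = t1.clades[i], t1.clades[i + 1]
        if lo & up == lo:  # joined by an edge: only an NNI could act here
            return False
        return t1.lengths[_interval_between(t1, i)] == 1
    return False


# ---------------------------------------------------------------------------
# move logs
# ---------------------------------------------------------------------------


def format_move_log(moves: Iterable[Move]) -> str:
    """One move per line: ``kind<TAB>interval_index`` (replayable)."""
    return "\n".join(f"{mv.kind.value}\t{mv.interval}" for mv in moves)


def parse_move_log(text: str) -> list[Move]:
    out = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        kind, _, idx = line.partition("\t")
        out.append(Move(MoveKind(kind), int(idx)))
    return out


def replay_moves(tree: DiscreteTimeTree, moves: Sequence[Move]) -> list[DiscreteTimeTree]:
    """Apply a move sequence, returning the full trajectory (incl. start)."""
    out = [tree]
    for mv in moves:
        out.append(apply_move(out[-1], mv))
    return out
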