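"""Constructive paths between ranked ultrametric trees.

``construct_path`` builds an explicit (not necessarily shortest) RNNIu
path from a source tree to a target tree by settling the target's clades
in rank order: for the clade of target rank k, the most recent common
ancestor of that taxon set in the running tree is driven down one rank at
a time — a rank swap when the node below is not its child, otherwise the
NNI move that keeps the target taxon set together — until it sits at rank
k with exactly the target clade.  Settled ranks are never touched again,
so stage k needs at most n-1-k moves and the whole path has length at
most (n-1)(n-2)/2, which is below the diameter upper bound
n^2 - 3n - 5/8 for every n >= 4.

The same machinery sorts a tree towards a caterpillar on a chosen leaf
subset (the building block of divide-and-conquer path arguments).
"""

from __future__ import annotations

from dataclasses import dataclass

from .space import Family, SpaceSpec
from .moves import Move, MoveKind, apply_move, is_adjacent
from .trees import DiscreteTimeTree, TreeError, trees_equal

__all__ = [
    "PathReport",
    "PathValidation",
    "diameter_upper_bound",
    "construct_path",
    "sort_to_caterpillar",
    "validate_path",
]


def diameter_upper_bound(n: int) -> float:
    """Upper bound n^2 - 3n - 5/8 on the RNNIu diameter, for n >= 4."""
    if n < 4:
        raise ValueError("the diameter upper bound needs n >= 4")
    return n * n - 3 * n - 5 / 8


@dataclass(frozen=True)
class PathReport:
    """A walk in a tree graph: trees plus the parallel move list."""

    trees: tuple[DiscreteTimeTree, ...]
    moves: tuple[Move, ...]

    @property
    def source(self) -> DiscreteTimeTree:
        return self.trees[0]

    @property
    def target(self) -> DiscreteTimeTree:
        return self.trees[-1]

    @property
    def length(self) -> int:
        return len(self.moves)


@dataclass(frozen=True)
class PathValidation:
    ok: bool
    violations: tuple[str, ...] = ()

    def __bool__(self) -> bool:
        return self.ok


# ---------------------------------------------------------------------------
# the greedy clade-settling walk
# ---------------------------------------------------------------------------


def _children_in(clades: list[int], pos: int) -> tuple[int, int]:
    """Two child masks of the internal node at ``pos`` (ultrametric list)."""
    c = clades[pos]
    rem = c
    kids = []
    for q in range(pos - 1, -1, -1):
        m = clades[q]
        if m & rem == m:
            kids.append(m)
            rem &= ~m
            if rem == 0:
                break
    while rem:  # leaf children
        low = rem & -rem
        kids.append(low)
        rem &= ~low
    kids.sort(key=lambda m: m & -m)
    return kids[0], kids[1]


def _greedy_steps(
    src: tuple[int, ...], dst: tuple[int, ...]
) -> list[tuple[MoveKind, int, tuple[int, ...]]]:
    """Move kinds, interval indices and successive clade tuples, src -> dst."""
    cur = list(src)
    steps: list[tuple[MoveKind, int, tuple[int, ...]]] = []
    for k, want in enumerate(dst):
        pos = k
        while cur[pos] & want != want:
            pos += 1
        while pos > k:
            low = pos - 1
            lo, up = cur[low], cur[pos]
            if lo & up == lo:
                # lo is a child of the mrca: NNI keeping `want` together
                k0, k1 = _children_in(cur, low)
                w = up & ~lo
                inner = want & lo
                keep = k0 if inner & k0 == inner else k1
                cur[low] = keep | w
                kind = MoveKind.NNI_A if keep == k1 else MoveKind.NNI_B
            else:
                cur[low], cur[pos] = cur[pos], cur[low]
                kind = MoveKind.RANK_SWAP
            # ultrametric event interval below the upper node: index low + 1
            steps.append((kind, low + 1, tuple(cur)))
            pos = low
    return steps


def construct_path(t1: DiscreteTimeTree, t2: DiscreteTimeTree) -> PathReport:
    """Explicit RNNIu path from ``t1`` to ``t2``; length <= (n-1)(n-2)/2.

    Every consecutive pair is adjacent (one rank swap or one NNI move) and
    the reported move list replays to the same trajectory.  The path is
    deterministic and need not be shortest, but its length never exceeds
    the diameter upper bound for n >= 4.
    """
    if t1.space.family is not Family.RNNIU or t2.space.family is not Family.RNNIU:
        raise TreeError("path construction is defined on RNNIu trees")
    if t1.labels != t2.labels:
        raise TreeError("trees are on different label sets")
    if trees_equal(t1, t2):
        return PathReport((t1,), ())
    steps = _greedy_steps(t1.clades, t2.clades)
    unit = t1.lengths
    trees = [t1]
    moves = []
    for kind, interval, clades in steps:
        moves.append(Move(kind, interval))
        trees.append(DiscreteTimeTree(t1.labels, clades, unit, t1.space))
    return PathReport(tuple(trees), tuple(moves))


# ---------------------------------------------------------------------------
# sorting towards caterpillars
# ---------------------------------------------------------------------------


def _restrict_clades(tree: DiscreteTimeTree, keep_mask: int) -> list[int]:
    """Internal clades of the tree induced on the kept leaves, rank order."""
    restricted: list[int] = []
    # restricted view of each subtree root as the sequence is replayed
    view: dict[int, int] = {}
    for pos, c in enumerate(tree.clades):
        k0, k1 = _children_in(list(tree.clades[: pos + 1]), pos)
        r0 = view.get(k0, k0 & keep_mask)
        r1 = view.get(k1, k1 & keep_mask)
        view[c] = r0 | r1
        if r0 and r1:
            restricted.append(r0 | r1)
    return restricted


def sort_to_caterpillar(tree: DiscreteTimeTree, order: list[str]) -> PathReport:
    """Path making the given leaves a top caterpillar in the given order.

    The endpoint restricted to ``order`` is a caterpillar with ``order[0]``
    innermost, sitting above the tree induced on the remaining leaves
    (whose relative ranked shape is preserved).  A subset of size <= 1
    already satisfies the condition, giving the empty path.
    """
    if tree.space.family is not Family.RNNIU:
        raise TreeError("caterpillar sorting is defined on RNNIu trees")
    if len(set(order)) != len(order) or not set(order) <= set(tree.labels):
        raise TreeError("order must list distinct leaves of the tree")
    if len(order) <= 1:
        return PathReport((tree,), ())
    index = {lab: i for i, lab in enumerate(tree.labels)}
    subset_mask = 0
    for lab in order:
        subset_mask |= 1 << index[lab]
    rest_mask = tree.full_mask & ~subset_mask

    if rest_mask == 0:
        bottom: list[int] = []
        spine_base = 0
        spine_order = order
    else:
        bottom = _restrict_clades(tree, rest_mask)
        spine_base = rest_mask
        spine_order = order
    target = list(bottom)
    acc = spine_base
    for lab in spine_order:
        acc |= 1 << index[lab]
        if acc.bit_count() >= 2:
            target.append(acc)
    # rest_mask may be a single leaf: then the first spine clade is a cherry
    dst = DiscreteTimeTree(tree.labels, tuple(target), tree.lengths, tree.space)
    dst.validate()
    return construct_path(tree, dst)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def validate_path(
    path: PathReport,
    space: SpaceSpec | None = None,
    check_moves: bool = True,
) -> PathValidation:
    """Check adjacency of consecutive trees and replayability of the moves.

    ``check_moves=False`` skips the (costlier) move-replay confirmation and
    validates the tree sequence alone; mass sweeps use that mode after the
    replay property has been established on smaller instances.
    """
    problems: list[str] = []
    trees = path.trees
    if not trees:
        return PathValidation(False, ("empty path report",))
    if space is not None and any(t.space != space for t in trees):
        problems.append(f"trees do not all live in {space}")
    if path.moves and len(path.moves) != len(trees) - 1:
        problems.append("move list length does not match tree count - 1")
    for i in range(len(trees) - 1):
        if not is_adjacent(trees[i], trees[i + 1]):
            problems.append(f"trees {i} and {i + 1} are not adjacent")
            break
    if check_moves and path.moves and not problems:
        for i, mv in enumerate(path.moves):
            stepped = apply_move(trees[i], mv)
            if not trees_equal(stepped, trees[i + 1]):
                problems.append(f"move {i} does not replay to tree {i + 1}")
                break
    return PathValidation(not problems, tuple(problems))
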