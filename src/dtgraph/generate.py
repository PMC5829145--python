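"""Seeded random tree generation.

Ranked topologies are drawn uniformly by running the discrete coalescent
backwards: starting from the n leaf lineages, merge a uniformly chosen
unordered pair at each of the n-1 steps.  Tip-dated (RNNI) trees extend
the draw with a uniformly chosen valid interleaving of the leaf ranks (a
linear extension sampled exactly by dynamic-programming counts).  DtT
interval lengths are i.i.d. uniform on {1..m}.  All randomness flows from
one ``random.Random`` instance, so a fixed seed gives byte-identical
output.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from functools import lru_cache

from .space import Family, SpaceSpec
from .trees import DiscreteTimeTree, TreeError

__all__ = ["GeneratorConfig", "random_tree", "random_trees"]


@dataclass(frozen=True)
class GeneratorConfig:
    n: int
    space: SpaceSpec
    seed: int
    count: int = 1

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.count < 1:
            raise ValueError("count must be >= 1")


def _coalescent_merge_order(n: int, rng: random.Random) -> tuple[int, ...]:
    """Uniform ranked topology: merged clade masks in rank order."""
    lineages = [1 << i for i in range(n)]
    clades = []
    while len(lineages) > 1:
        i, j = sorted(rng.sample(range(len(lineages)), 2))
        merged = lineages[i] | lineages[j]
        lineages = [x for k, x in enumerate(lineages) if k not in (i, j)]
        lineages.append(merged)
        clades.append(merged)
    return tuple(clades)


def _interleave_leaves(
    clades: tuple[int, ...], n: int, rng: random.Random
) -> tuple[int, ...]:
    """Insert the n leaf events into the ranked internal sequence.

    The interleaving is uniform over linear extensions of the node order
    (each leaf strictly before its parent, internal order fixed).  Sampled
    backwards from the root with exact completion counts: remove either
    the highest remaining internal node (freeing its leaf children) or any
    already-freed leaf, weighting choices by the number of completions.
    """
    # parent of each leaf = first internal clade containing it
    leaf_kids: dict[int, list[int]] = {i: [] for i in range(len(clades))}
    for bit in range(n):
        mask = 1 << bit
        for pos, c in enumerate(clades):
            if c & mask:
                leaf_kids[pos].append(mask)
                break
    top = list(range(len(clades) - 1, -1, -1))  # positions from root down
    lc = [len(leaf_kids[pos]) for pos in top]

    @lru_cache(maxsize=None)
    def completions(t: int, f: int) -> int:
        if t == len(top):
            out = 1
            for k in range(2, f + 1):
                out *= k
            return out
        total = completions(t + 1, f + lc[t])
        if f:
            total += f * completions(t, f - 1)
        return total

    removal: list[int] = []  # masks, from the root downwards
    free: list[int] = []
    t, f = 0, 0
    while t < len(top) or free:
        w_int = completions(t + 1, f + lc[t]) if t < len(top) else 0
        total = w_int + (f * completions(t, f - 1) if f else 0)
        pick = rng.randrange(total)
        if pick < w_int:
            pos = top[t]
            removal.append(clades[pos])
            free.extend(sorted(leaf_kids[pos]))
            t += 1
            f = len(free)
        else:
            idx = (pick - w_int) // completions(t, f - 1)
            removal.append(free.pop(idx))
            f = len(free)
    completions.cache_clear()
    return tuple(reversed(removal))


def random_tree(
    n: int,
    space: SpaceSpec,
    rng: random.Random | int,
    labels: list[str] | None = None,
) -> DiscreteTimeTree:
    """One random tree of the space on n leaves (labels default "1".."n")."""
    if isinstance(rng, int):
        rng = random.Random(rng)
    if n < 2:
        raise ValueError("n must be >= 2")
    if labels is None:
        labels = [str(i) for i in range(1, n + 1)]
    labs = tuple(sorted(labels))
    if len(labs) != n:
        raise TreeError("need n distinct labels")

    clades = _coalescent_merge_order(n, rng)
    if space.family is Family.NNI:
        key = tuple(sorted(clades, key=lambda m: (m.bit_count(), m)))
        return DiscreteTimeTree(labs, key, (), space)
    if not space.is_ultrametric:
        clades = _interleave_leaves(clades, n, rng)
    n_int = space.n_intervals(n)
    if space.has_lengths:
        lengths = tuple(rng.randint(1, space.m) for _ in range(n_int))
    else:
        lengths = (1,) * n_int
    return DiscreteTimeTree(labs, clades, lengths, space)


def random_trees(config: GeneratorConfig, labels: list[str] | None = None):
    """Deterministic list of ``config.count`` trees from ``config.seed``."""
    rng = random.Random(config.seed)
    return [random_tree(config.n, config.space, rng, labels) for _ in range(config.count)]
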