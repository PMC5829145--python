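"""Empirical verifiers for structural claims about time-tree graphs.

Each checker enumerates a space exactly, decides a property over the
stated instance set and returns a machine-readable
:class:`PropertyReport`.  The interesting claims:

* **split preservation** — if a leaf bipartition (given by an edge) is
  present in two trees, is it present in every tree on every shortest
  path between them?  Believed true in the ranked families and known to
  fail in plain NNI at large n.
* **closer-neighbour bounds** — conditional on split preservation, the
  number of neighbours of x not further from y is at most 3 d(x,y) in
  RNNI, 4 d(x,y) at interval cap m=2 and 5 d(x,y) for m>2.
* **caterpillar convexity** — caterpillars with a fixed innermost and
  outermost leaf admit within-set shortest paths in the ranked families
  but not in NNI.
* **degree/count tightness** — enumerated vertex counts and degree
  extremes match the closed forms, with the named extremal constructions
  attaining the bounds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations, permutations
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .space import Family, SpaceSpec
from .moves import degree, degree_bounds, neighbors
from .spaces import TreeGraph, bfs_distance, build_graph, count_trees, enumerate_trees
from .trees import (
    DiscreteTimeTree,
    TreeError,
    alternating_caterpillar,
    canonical_key,
    caterpillar_tree,
    low_degree_tree,
    max_length_tree,
)

__all__ = [
    "PropertyReport",
    "convex_set_violations",
    "check_split_conjecture",
    "closer_neighbor_count",
    "check_closer_neighbors",
    "check_caterpillar_convexity",
    "verify_degree_and_count_claims",
    "reports_to_jsonl",
]


@dataclass(frozen=True)
class PropertyReport:
    """Outcome of one property check over one space at one size."""

    name: str
    space: str
    n: int
    instances_checked: int
    counterexamples: tuple = ()
    verdict: str = "holds"  # holds | fails | inconclusive
    details: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "property": self.name,
                "space": self.space,
                "n": self.n,
                "instances_checked": self.instances_checked,
                "counterexamples": list(self.counterexamples),
                "verdict": self.verdict,
                "details": self.details,
            },
            sort_keys=True,
        )


def reports_to_jsonl(reports: Iterable[PropertyReport]) -> str:
    return "\n".join(r.to_json() for r in reports) + "\n"


def _verdict(counterexamples: Sequence) -> str:
    return "fails" if counterexamples else "holds"


# ---------------------------------------------------------------------------
# split preservation on shortest paths
# ---------------------------------------------------------------------------


def _split_keys(tree: DiscreteTimeTree) -> frozenset[int]:
    """Nontrivial leaf partitions of a tree, one per edge.

    In a rooted tree the partition given by an edge is (clade below the
    edge) | (rest), so it is identified by the clade mask.  Singleton
    clades and the full leaf set occur in every tree and are dropped.
    """
    n = tree.n
    return frozenset(c for c in tree.clades if 2 <= c.bit_count() <= n - 1)


def convex_set_violations(
    adjacency: csr_matrix,
    members: np.ndarray,
    chunk: int = 128,
    max_found: int = 1,
) -> list[tuple[int, int, int]]:
    """Find (t, u, v): u,t in the set, v outside, on a shortest u-t path.

    A shortest path between members leaves the set iff it does so at its
    first exit edge, i.e. iff there are members t, u and a non-member
    neighbour v of u with d(t, v) < d(t, u).  Works on any undirected
    graph, which lets the checker itself be validated on synthetic graphs
    with planted violations.
    """
    members = np.asarray(members, dtype=bool)
    member_idx = np.flatnonzero(members)
    if member_idx.size == 0:
        return []
    indptr, indices = adjacency.indptr, adjacency.indices
    boundary_u, boundary_v = [], []
    for u in member_idx:
        for v in indices[indptr[u] : indptr[u + 1]]:
            if not members[v]:
                boundary_u.append(u)
                boundary_v.append(v)
    if not boundary_u:
        return []
    bu = np.array(boundary_u)
    bv = np.array(boundary_v)
    found: list[tuple[int, int, int]] = []
    for start in range(0, member_idx.size, chunk):
        sources = member_idx[start : start + chunk]
        d = dijkstra(adjacency, directed=False, unweighted=True, indices=sources)
        bad = d[:, bv] < d[:, bu]  # v strictly closer to t than u is
        if bad.any():
            for row, col in zip(*np.nonzero(bad)):
                found.append((int(sources[row]), int(bu[col]), int(bv[col])))
                if len(found) >= max_found:
                    return found
    return found


def _witness_path(graph: TreeGraph, t: int, u: int, v: int) -> tuple[str, ...]:
    """A shortest u->t path through v, as canonical keys."""
    d_to_t = dijkstra(graph.csr(), directed=False, unweighted=True, indices=[t])[0]
    path = [u, v]
    cur = v
    while cur != t:
        for w in graph.adj[cur]:
            if d_to_t[w] == d_to_t[cur] - 1:
                path.append(w)
                cur = w
                break
    return tuple(graph.keys[i] for i in path)


def check_split_conjecture(
    n: int,
    space: SpaceSpec,
    exhaustive_splits: bool = False,
    max_vertices: int | None = None,
    graph: TreeGraph | None = None,
) -> PropertyReport:
    """Do all shortest paths preserve every shared nontrivial bipartition?

    Exhaustive over the space: for every bipartition class and every pair
    of trees presenting it, every tree on every shortest path between
    them is inspected (via the first-exit-edge criterion, equivalent to
    walking the full shortest-path DAG).  By default one representative
    bipartition per size class is checked; the graphs are
    label-permutation symmetric, so this loses no generality
    (set ``exhaustive_splits=True`` to check all of them anyway).
    """
    if graph is None:
        kwargs = {} if max_vertices is None else {"max_vertices": max_vertices}
        graph = build_graph(n, space, **kwargs)
    full = (1 << n) - 1
    if exhaustive_splits:
        splits = [c for c in range(3, full) if 2 <= bin(c).count("1") <= n - 1]
    else:
        # one representative clade per size; label permutations are graph
        # automorphisms, so each size class is covered by its representative
        splits = [(1 << s) - 1 for s in range(2, n)]
    part_sets = [_split_keys(t) for t in graph.trees]
    adjacency = graph.csr()
    counterexamples = []
    instances = 0
    for split in splits:
        members = np.fromiter((split in ps for ps in part_sets), bool, len(part_sets))
        h = int(members.sum())
        instances += h * (h - 1) // 2
        for t, u, v in convex_set_violations(adjacency, members):
            counterexamples.append(
                {
                    "split": split,
                    "pair": [graph.keys[u], graph.keys[t]],
                    "offending_path": list(_witness_path(graph, t, u, v)),
                }
            )
    return PropertyReport(
        name="split_preservation",
        space=str(space),
        n=n,
        instances_checked=instances,
        counterexamples=tuple(json.dumps(c, sort_keys=True) for c in counterexamples),
        verdict=_verdict(counterexamples),
        details={
            "split_classes": len(splits),
            "symmetry_reduced": not exhaustive_splits,
            "vertices": graph.vertex_count,
        },
    )


# ---------------------------------------------------------------------------
# closer-neighbour counts
# ---------------------------------------------------------------------------


def _closer_bound_factor(space: SpaceSpec) -> int:
    if space.family in (Family.RNNI, Family.RNNIU):
        return 3
    if space.has_lengths:
        return 4 if space.m == 2 else 5
    raise TreeError("closer-neighbour bounds are stated for the ranked families")


def closer_neighbor_count(
    x: DiscreteTimeTree, y: DiscreteTimeTree, space: SpaceSpec | None = None
) -> int:
    """|{u in N(x) : d(u, y) <= d(x, y)}| by explicit BFS distances."""
    if space is not None and (x.space != space or y.space != space):
        raise TreeError("trees do not live in the requested space")
    dxy = bfs_distance(x, y)
    count = 0
    for u in neighbors(x):
        if bfs_distance(u, y) <= dxy:
            count += 1
    return count


def check_closer_neighbors(
    n: int,
    space: SpaceSpec,
    max_vertices: int | None = None,
    graph: TreeGraph | None = None,
    chunk: int = 512,
) -> PropertyReport:
    """Closer-neighbour counts against the 3d/4d/5d envelope, all pairs.

    The bound is conditional on split preservation, so excesses are
    recorded as counterexample evidence (they would bear on that
    conjecture) rather than raised as errors.
    """
    factor = _closer_bound_factor(space)
    if graph is None:
        kwargs = {} if max_vertices is None else {"max_vertices": max_vertices}
        graph = build_graph(n, space, **kwargs)
    nv = graph.vertex_count
    dist = graph.all_distances(chunk=chunk)  # (nv, nv); sizes guarded upstream
    counterexamples = []
    instances = 0
    worst_ratio = 0.0
    for x in range(nv):
        nbr = list(graph.adj[x])
        if not nbr:
            continue
        dx = dist[x]  # d(x, y) over all y
        closer = (dist[nbr] <= dx[None, :]).sum(axis=0)  # |{u in N(x): d(u,y)<=d(x,y)}|
        ys = np.flatnonzero(dx > 0)
        instances += ys.size
        bad = ys[closer[ys] > factor * dx[ys]]
        if ys.size:
            worst_ratio = max(worst_ratio, float((closer[ys] / dx[ys]).max()))
        for y in bad[:5]:
            counterexamples.append(
                json.dumps(
                    {
                        "x": graph.keys[x],
                        "y": graph.keys[int(y)],
                        "count": int(closer[int(y)]),
                        "distance": int(dx[int(y)]),
                        "bound": int(factor * dx[int(y)]),
                    },
                    sort_keys=True,
                )
            )
    return PropertyReport(
        name="closer_neighbors",
        space=str(space),
        n=n,
        instances_checked=instances,
        counterexamples=tuple(counterexamples),
        verdict=_verdict(counterexamples),
        details={"bound_factor": factor, "worst_ratio": worst_ratio},
    )


# ---------------------------------------------------------------------------
# caterpillar convexity
# ---------------------------------------------------------------------------


def fixed_form_caterpillars(n: int, space: SpaceSpec) -> list[DiscreteTimeTree]:
    """Caterpillars with the smallest leaf innermost, largest outermost."""
    labels = [str(i) for i in range(1, n + 1)]
    out = []
    for middle in permutations(labels[1:-1]):
        order = [labels[0], *middle, labels[-1]]
        out.append(caterpillar_tree(space, order))
    return out


def _restricted_distance(
    t1: DiscreteTimeTree, t2: DiscreteTimeTree, allowed: set
) -> int | None:
    """BFS distance inside the subgraph induced on ``allowed`` keys."""
    k1, k2 = canonical_key(t1), canonical_key(t2)
    if k1 == k2:
        return 0
    seen = {k1}
    frontier = [t1]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for t in frontier:
            for nb in neighbors(t):
                k = canonical_key(nb)
                if k in seen or k not in allowed:
                    continue
                if k == k2:
                    return d
                seen.add(k)
                nxt.append(nb)
        frontier = nxt
    return None


def check_caterpillar_convexity(
    n: int,
    space: SpaceSpec,
    pairs: Sequence[tuple[DiscreteTimeTree, DiscreteTimeTree]] | None = None,
) -> PropertyReport:
    """Does some shortest path between fixed-form caterpillars stay in form?

    For each pair the within-set distance (BFS restricted to fixed-form
    caterpillars) is compared with the unrestricted distance; equality
    exhibits a convexity witness.  Default instance set: all pairs of
    fixed-form caterpillars.
    """
    cats = fixed_form_caterpillars(n, space)
    allowed = {canonical_key(t) for t in cats}
    if pairs is None:
        pairs = list(combinations(cats, 2))
    counterexamples = []
    records = []
    for t1, t2 in pairs:
        if canonical_key(t1) not in allowed or canonical_key(t2) not in allowed:
            raise TreeError("pair is not of the fixed caterpillar form")
        d_global = bfs_distance(t1, t2)
        d_inside = _restricted_distance(t1, t2, allowed)
        witness = d_inside is not None and d_inside == d_global
        records.append(
            {
                "pair": [canonical_key(t1), canonical_key(t2)],
                "distance": d_global,
                "within_set_distance": d_inside,
                "witness": witness,
            }
        )
        if not witness:
            counterexamples.append(json.dumps(records[-1], sort_keys=True))
    return PropertyReport(
        name="caterpillar_convexity",
        space=str(space),
        n=n,
        instances_checked=len(records),
        counterexamples=tuple(counterexamples),
        verdict=_verdict(counterexamples),
        details={"set_size": len(cats), "pairs": records if len(records) <= 8 else []},
    )


# ---------------------------------------------------------------------------
# degree and count tightness
# ---------------------------------------------------------------------------


def _interval_degree_span(tree: DiscreteTimeTree, m: int) -> tuple[int, int]:
    """Min/max degree over all length assignments of one ranked tree.

    Per interval the degree contribution depends only on its own length:
    1 + c at length 1 (c = 2 NNI, 1 rank swap or 0), 1 at length m and 2
    strictly between, so extremes factorise over intervals.
    """
    from .moves import applicable_moves, MoveKind

    contrib = {}
    for mv in applicable_moves(tree):
        if mv.kind in (MoveKind.NNI_A, MoveKind.NNI_B, MoveKind.RANK_SWAP):
            contrib[mv.interval] = contrib.get(mv.interval, 0) + 1
    lo = hi = 0
    for i in range(len(tree.lengths)):
        c = contrib.get(i, 0)
        options = [1 + c, 1] + ([2] if m > 2 else [])
        lo += min(options)
        hi += max(options)
    return lo, hi


def verify_degree_and_count_claims(
    n: int,
    space: SpaceSpec,
    max_vertices: int | None = None,
) -> PropertyReport:
    """Vertex count, degree envelope tightness and extremal constructions.

    Enumerates the space (for DtT/DtTu, ranked shapes with the length
    dimension factorised out — exact, since length assignments only shift
    per-interval contributions) and compares observed degree extremes and
    counts with the closed forms; then checks that the named extremal
    trees attain them.
    """
    lo_bound, hi_bound = degree_bounds(n, space)
    expected_count = count_trees(n, space)
    labels = [str(i) for i in range(1, n + 1)]

    if space.has_lengths:
        ranked = SpaceSpec.rnniu() if space.is_ultrametric else SpaceSpec.rnni()
        kwargs = {} if max_vertices is None else {"max_vertices": max_vertices}
        seen = 0
        lo = hi = None
        for base in enumerate_trees(n, ranked, labels=labels, **kwargs):
            lifted = DiscreteTimeTree(base.labels, base.clades, base.lengths, space)
            a, b = _interval_degree_span(lifted, space.m)
            seen += 1
            lo = a if lo is None else min(lo, a)
            hi = b if hi is None else max(hi, b)
        observed_count = seen * space.m ** space.n_intervals(n)
    else:
        kwargs = {} if max_vertices is None else {"max_vertices": max_vertices}
        lo = hi = None
        observed_count = 0
        for t in enumerate_trees(n, space, labels=labels, **kwargs):
            d = degree(t)
            observed_count += 1
            lo = d if lo is None else min(lo, d)
            hi = d if hi is None else max(hi, d)

    extremal = {}
    family = space.family
    if family is Family.NNI:
        extremal["caterpillar"] = degree(caterpillar_tree(space, labels))
    elif family is Family.RNNI:
        extremal["alternating_caterpillar"] = degree(alternating_caterpillar(space, labels))
        extremal["caterpillar"] = degree(caterpillar_tree(space, labels))
    elif family is Family.RNNIU:
        extremal["two_branch"] = degree(low_degree_tree(space, labels))
        extremal["caterpillar"] = degree(caterpillar_tree(space, labels))
    elif family is Family.DTT:
        extremal["all_intervals_max"] = degree(max_length_tree(space, labels))
        base = caterpillar_tree(SpaceSpec.rnni(), labels)
        extremal["caterpillar_unit"] = degree(
            DiscreteTimeTree(base.labels, base.clades, base.lengths, space)
        )
    elif family is Family.DTTU:
        extremal["all_intervals_max"] = degree(max_length_tree(space, labels))
        base = caterpillar_tree(SpaceSpec.rnniu(), labels)
        extremal["caterpillar_unit"] = degree(
            DiscreteTimeTree(base.labels, base.clades, base.lengths, space)
        )

    problems = []
    if observed_count != expected_count:
        problems.append(f"count {observed_count} != closed form {expected_count}")
    if (lo, hi) != (lo_bound, hi_bound):
        problems.append(f"degree extremes ({lo},{hi}) != bounds ({lo_bound},{hi_bound})")
    vals = set(extremal.values())
    if family is Family.NNI:
        if vals != {lo_bound}:
            problems.append(f"NNI construction degree {vals} != {lo_bound}")
    else:
        if lo_bound not in vals or hi_bound not in vals:
            problems.append(f"constructions {extremal} miss a bound ({lo_bound},{hi_bound})")

    return PropertyReport(
        name="degree_and_count_tightness",
        space=str(space),
        n=n,
        instances_checked=expected_count,
        counterexamples=tuple(problems),
        verdict=_verdict(problems),
        details={
            "count": observed_count,
            "degree_min": lo,
            "degree_max": hi,
            "bounds": [lo_bound, hi_bound],
            "extremal_degrees": extremal,
        },
    )
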