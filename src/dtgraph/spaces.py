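"""Whole-graph construction and exact geometry at enumerable sizes.

Every space in the hierarchy is finite for fixed n, so for small n the
graphs can be built outright: vertices are canonical clade sequences,
edges the single-move adjacencies.  These exact graphs serve as the
ground-truth oracle for the closed-form vertex counts, the degree
envelope, neighbourhood-size bounds and diameter bounds.

Enumeration strategies:

* ranked ultrametric trees are generated as coalescent merge sequences
  (choose an unordered pair of lineages at each of the n-1 steps), which
  visits every ranked topology exactly once;
* tip-dated ranked trees interleave "sample a leaf" events with merges;
* DtT trees cross the ranked enumeration with all interval-length
  assignments in {1..m};
* NNI topologies deduplicate the ranked enumeration.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from .space import Family, SpaceSpec
from .moves import neighbors
from .trees import (
    DiscreteTimeTree,
    TreeError,
    canonical_key,
    tree_from_canonical,
    trees_equal,
)

__all__ = [
    "SizeGuardError",
    "count_trees",
    "enumerate_trees",
    "TreeGraph",
    "build_graph",
    "bfs_distance",
    "diameter",
    "neighborhood_size",
    "rneighborhood_bound",
    "diameter_lower_bound",
]


class SizeGuardError(RuntimeError):
    """A requested exact computation exceeds the configured size guard."""


DEFAULT_MAX_VERTICES = 300_000
DEFAULT_MAX_EXPLORED = 2_000_000


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _ranked_tipdated_count(n_leaves: int) -> int:
    """Number of ranked tip-dated trees: DP over (unplaced leaves, roots).

    Events in rank order either sample one of the remaining distinguishable
    leaves or merge an unordered pair of current lineages.
    """

    @lru_cache(maxsize=None)
    def f(unplaced: int, roots: int) -> int:
        if unplaced == 0 and roots == 1:
            return 1
        total = 0
        if unplaced:
            total += unplaced * f(unplaced - 1, roots + 1)
        if roots >= 2:
            total += roots * (roots - 1) // 2 * f(unplaced, roots - 1)
        return total

    return f(n_leaves, 0)


def count_trees(n: int, space: SpaceSpec) -> int:
    """Exact number of trees on n leaves in the space (closed form / DP).

    NNI: (2n-3)!!.  RNNIu: n!(n-1)!/2^(n-1) (coalescent histories).  RNNI:
    rank-sequence DP.  DtT_m and DtTu_m multiply by m per event interval.
    Cross-checked against exhaustive enumeration in the test suite.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        return 1
    family = space.family
    if family is Family.NNI:
        out = 1
        for k in range(3, 2 * n - 2, 2):
            out *= k
        return out
    if family is Family.RNNIU:
        return math.factorial(n) * math.factorial(n - 1) // 2 ** (n - 1)
    if family is Family.RNNI:
        return _ranked_tipdated_count(n)
    if family is Family.DTTU:
        return count_trees(n, SpaceSpec.rnniu()) * space.m ** (n - 1)
    if family is Family.DTT:
        return count_trees(n, SpaceSpec.rnni()) * space.m ** (2 * n - 2)
    raise ValueError(f"unknown family {family}")


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------


def _merge_sequences(roots: tuple[int, ...]) -> Iterator[tuple[int, ...]]:
    """All coalescent merge orders of the given lineages (clades emitted)."""
    if len(roots) == 1:
        yield ()
        return
    for i, j in itertools.combinations(range(len(roots)), 2):
        merged = roots[i] | roots[j]
        rest = tuple(r for k, r in enumerate(roots) if k != i and k != j) + (merged,)
        for tail in _merge_sequences(rest):
            yield (merged,) + tail


def _tipdated_sequences(n: int) -> Iterator[tuple[int, ...]]:
    leaves = tuple(1 << i for i in range(n))

    def rec(unused: tuple[int, ...], roots: tuple[int, ...]) -> Iterator[tuple[int, ...]]:
        if not unused and len(roots) == 1:
            yield ()
            return
        for idx, lf in enumerate(unused):
            rest = unused[:idx] + unused[idx + 1 :]
            for tail in rec(rest, roots + (lf,)):
                yield (lf,) + tail
        for i, j in itertools.combinations(range(len(roots)), 2):
            merged = roots[i] | roots[j]
            new_roots = tuple(r for k, r in enumerate(roots) if k != i and k != j) + (merged,)
            for tail in rec(unused, new_roots):
                yield (merged,) + tail

    yield from rec(leaves, ())


def enumerate_trees(
    n: int,
    space: SpaceSpec,
    labels: Sequence[str] | None = None,
    max_vertices: int | None = DEFAULT_MAX_VERTICES,
) -> Iterator[DiscreteTimeTree]:
    """Yield every tree of the space on n leaves, valid by construction.

    Default labels are "1".."n".  The guard compares the closed-form count
    against ``max_vertices`` before any work (pass None to disable).
    """
    if n < 2:
        raise ValueError("enumeration needs n >= 2")
    if max_vertices is not None:
        total = count_trees(n, space)
        if total > max_vertices:
            raise SizeGuardError(
                f"{total} trees in {space} at n={n} exceeds guard {max_vertices}"
            )
    if labels is None:
        labels = [str(i) for i in range(1, n + 1)]
    labs = tuple(sorted(labels))
    if len(labs) != n:
        raise TreeError("need n distinct labels")
    family = space.family

    if family is Family.NNI:
        seen = set()
        for seq in _merge_sequences(tuple(1 << i for i in range(n))):
            key = tuple(sorted(seq, key=lambda m: (m.bit_count(), m)))
            if key not in seen:
                seen.add(key)
                yield DiscreteTimeTree(labs, key, (), space)
        return

    if space.is_ultrametric:
        sequences: Iterable[tuple[int, ...]] = _merge_sequences(
            tuple(1 << i for i in range(n))
        )
    else:
        sequences = _tipdated_sequences(n)

    n_int = space.n_intervals(n)
    unit = (1,) * n_int
    for seq in sequences:
        if space.has_lengths:
            for lens in itertools.product(range(1, space.m + 1), repeat=n_int):
                yield DiscreteTimeTree(labs, seq, lens, space)
        else:
            yield DiscreteTimeTree(labs, seq, unit, space)


# ---------------------------------------------------------------------------
# explicit graphs
# ---------------------------------------------------------------------------


@dataclass
class TreeGraph:
    """Explicit move graph over canonical representations.

    Vertices are sorted lexicographically by canonical key, so builds are
    reproducible; ``adj`` holds sorted integer adjacency lists.
    """

    space: SpaceSpec
    n: int
    keys: tuple[str, ...]
    trees: tuple[DiscreteTimeTree, ...]
    adj: tuple[tuple[int, ...], ...]

    @property
    def vertex_count(self) -> int:
        return len(self.keys)

    @property
    def edge_count(self) -> int:
        return sum(len(a) for a in self.adj) // 2

    def degrees(self) -> list[int]:
        return [len(a) for a in self.adj]

    def index_of(self, tree: DiscreteTimeTree) -> int:
        return self.keys.index(canonical_key(tree))

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.vertex_count))
        for i, nbrs in enumerate(self.adj):
            for j in nbrs:
                if j > i:
                    g.add_edge(i, j)
        return g

    def csr(self) -> csr_matrix:
        indptr = [0]
        indices: list[int] = []
        for nbrs in self.adj:
            indices.extend(nbrs)
            indptr.append(len(indices))
        data = np.ones(len(indices), dtype=np.int8)
        nv = self.vertex_count
        return csr_matrix((data, np.array(indices), np.array(indptr)), shape=(nv, nv))

    def is_connected(self) -> bool:
        if self.vertex_count <= 1:
            return True
        ncomp, _ = connected_components(self.csr(), directed=False)
        return int(ncomp) == 1

    def distances_from(self, indices: Sequence[int], limit: float = np.inf) -> np.ndarray:
        """Hop-count distance matrix from the given source vertices."""
        return dijkstra(self.csr(), directed=False, unweighted=True,
                        indices=list(indices), limit=limit)

    def all_distances(self, chunk: int = 1024) -> np.ndarray:
        mat = self.csr()
        nv = self.vertex_count
        out = np.empty((nv, nv), dtype=np.float32)
        for start in range(0, nv, chunk):
            idx = list(range(start, min(start + chunk, nv)))
            out[start : start + len(idx)] = dijkstra(
                mat, directed=False, unweighted=True, indices=idx
            )
        return out

    def ball_sizes(self, r: int, chunk: int = 2048) -> np.ndarray:
        """|B_r(v)| for every vertex v (BFS truncated at depth r)."""
        mat = self.csr()
        nv = self.vertex_count
        out = np.empty(nv, dtype=np.int64)
        for start in range(0, nv, chunk):
            idx = list(range(start, min(start + chunk, nv)))
            d = dijkstra(mat, directed=False, unweighted=True, indices=idx, limit=r)
            out[start : start + len(idx)] = (d <= r).sum(axis=1)
        return out

    # -- serialisation -------------------------------------------------

    def write_edge_tsv(self) -> str:
        """TSV edge list of canonical-key pairs (plus isolated vertices)."""
        lines = []
        in_edge = [False] * self.vertex_count
        for i, nbrs in enumerate(self.adj):
            for j in nbrs:
                if j > i:
                    lines.append(f"{self.keys[i]}\t{self.keys[j]}")
                    in_edge[i] = in_edge[j] = True
        for i, used in enumerate(in_edge):
            if not used:
                lines.append(self.keys[i])
        return "\n".join(lines) + "\n"

    def write_dot(self, name: str = "treegraph") -> str:
        lines = [f'graph "{name}" {{']
        for i, key in enumerate(self.keys):
            lines.append(f'  v{i} [label="{key}"];')
        for i, nbrs in enumerate(self.adj):
            for j in nbrs:
                if j > i:
                    lines.append(f"  v{i} -- v{j};")
        lines.append("}")
        return "\n".join(lines) + "\n"

    @classmethod
    def read_edge_tsv(cls, text: str, space: SpaceSpec) -> "TreeGraph":
        """Rebuild a graph from the TSV edge-list form."""
        edges: list[tuple[str, str]] = []
        key_set: set[str] = set()
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            key_set.update(parts)
            if len(parts) == 2:
                edges.append((parts[0], parts[1]))
        keys = tuple(sorted(key_set))
        index = {k: i for i, k in enumerate(keys)}
        adj_sets: list[set[int]] = [set() for _ in keys]
        for a, b in edges:
            adj_sets[index[a]].add(index[b])
            adj_sets[index[b]].add(index[a])
        trees = tuple(tree_from_canonical(k, space) for k in keys)
        n = trees[0].n if trees else 0
        return cls(space, n, keys, trees, tuple(tuple(sorted(s)) for s in adj_sets))


def build_graph(
    n: int,
    space: SpaceSpec,
    labels: Sequence[str] | None = None,
    max_vertices: int = DEFAULT_MAX_VERTICES,
) -> TreeGraph:
    """Build the full move graph on all trees of the space at size n.

    The vertex set is the complete enumeration; edges come from the moves
    module, realised as canonical-key lookups (each tree's neighbours are
    generated and resolved against the vertex index).
    """
    trees = list(enumerate_trees(n, space, labels=labels, max_vertices=max_vertices))
    keyed = sorted(((canonical_key(t), t) for t in trees), key=lambda kt: kt[0])
    keys = tuple(k for k, _ in keyed)
    trees_sorted = tuple(t for _, t in keyed)
    index = {(t.clades, t.lengths): i for i, (_, t) in enumerate(keyed)}
    adj: list[list[int]] = [[] for _ in keys]
    for i, t in enumerate(trees_sorted):
        for nb in neighbors(t):
            j = index[(nb.clades, nb.lengths)]
            if j > i:
                adj[i].append(j)
                adj[j].append(i)
    return TreeGraph(space, n, keys, trees_sorted, tuple(tuple(sorted(a)) for a in adj))


# ---------------------------------------------------------------------------
# distances without full graphs
# ---------------------------------------------------------------------------


def bfs_distance(
    t1: DiscreteTimeTree,
    t2: DiscreteTimeTree,
    space: SpaceSpec | None = None,
    max_explored: int = DEFAULT_MAX_EXPLORED,
) -> int:
    """Exact shortest-path length by bidirectional breadth-first search.

    Explores neighbourhoods on the fly (no full graph materialisation);
    raises :class:`SizeGuardError` after ``max_explored`` expansions.
    """
    if space is not None:
        if t1.space != space or t2.space != space:
            raise TreeError("trees do not live in the requested space")
    if trees_equal(t1, t2):
        return 0

    def key(t: DiscreteTimeTree):
        return (t.clades, t.lengths)

    side_a = {key(t1): t1}
    side_b = {key(t2): t2}
    dist_a = {key(t1): 0}
    dist_b = {key(t2): 0}
    frontier_a, frontier_b = [t1], [t2]
    da = db = 0
    explored = 0
    while frontier_a and frontier_b:
        # expand the smaller frontier
        if len(frontier_a) <= len(frontier_b):
            frontier, dist_here, dist_other, d_here = frontier_a, dist_a, dist_b, da
        else:
            frontier, dist_here, dist_other, d_here = frontier_b, dist_b, dist_a, db
        new_frontier = []
        for t in frontier:
            for nb in neighbors(t):
                k = key(nb)
                if k in dist_here:
                    continue
                if k in dist_other:
                    return d_here + 1 + dist_other[k]
                dist_here[k] = d_here + 1
                new_frontier.append(nb)
                explored += 1
                if explored > max_explored:
                    raise SizeGuardError(
                        f"bidirectional BFS exceeded {max_explored} expansions"
                    )
        if frontier is frontier_a:
            frontier_a, da = new_frontier, da + 1
        else:
            frontier_b, db = new_frontier, db + 1
    raise TreeError("trees are not connected in this space (should not happen)")


def diameter(graph: TreeGraph) -> int:
    """Exact diameter (maximum eccentricity); errors on disconnected input."""
    if graph.vertex_count <= 1:
        return 0
    if not graph.is_connected():
        raise ValueError(f"graph over {graph.space} at n={graph.n} is disconnected")
    best = 0
    mat = graph.csr()
    chunk = 1024
    for start in range(0, graph.vertex_count, chunk):
        idx = list(range(start, min(start + chunk, graph.vertex_count)))
        d = dijkstra(mat, directed=False, unweighted=True, indices=idx)
        best = max(best, int(d.max()))
    return best


def neighborhood_size(
    tree: DiscreteTimeTree,
    r: int,
    space: SpaceSpec | None = None,
    max_explored: int = DEFAULT_MAX_EXPLORED,
) -> int:
    """|B_r(tree)|: number of trees within distance r (BFS to depth r)."""
    if space is not None and tree.space != space:
        raise TreeError(f"tree lives in {tree.space}, not {space}")
    if r < 0:
        raise ValueError("radius must be non-negative")
    seen = {(tree.clades, tree.lengths)}
    frontier = [tree]
    for _ in range(r):
        new_frontier = []
        for t in frontier:
            for nb in neighbors(t):
                k = (nb.clades, nb.lengths)
                if k not in seen:
                    seen.add(k)
                    new_frontier.append(nb)
                    if len(seen) > max_explored:
                        raise SizeGuardError(f"ball exceeded {max_explored} trees")
        frontier = new_frontier
    return len(seen)


# ---------------------------------------------------------------------------
# printed bounds
# ---------------------------------------------------------------------------


def _grammar_base_and_exponent(n: int, space: SpaceSpec) -> tuple[int, int]:
    """(a, f(n)) such that |B_r| <= a^(f(n) + 2r) in this space.

    The base counts node-labels of the underlying graph grammar: 3 for the
    ranked families, 4 once interval lengths join the alphabet; the
    exponent offset is the number of ranked nodes (n-1 ultrametric, 2n-1
    tip-dated).
    """
    family = space.family
    if family is Family.NNI:
        raise ValueError("no grammar bound is implemented for the NNI family")
    a = 3 if family in (Family.RNNI, Family.RNNIU) else 4
    f = n - 1 if space.is_ultrametric else 2 * n - 1
    return a, f


def rneighborhood_bound(n: int, r: int, space: SpaceSpec) -> int:
    """Closed-form upper bound on the r-neighbourhood size.

    RNNIu: 3^(n-1+2r); RNNI: 3^(2n-1+2r); DtTu_m: 4^(n-1+2r);
    DtT_m: 4^(2n-1+2r).  Monotone in n and r.
    """
    if r < 0:
        raise ValueError("radius must be non-negative")
    a, f = _grammar_base_and_exponent(n, space)
    return a ** (f + 2 * r)


def diameter_lower_bound(n: int, space: SpaceSpec) -> float:
    """Diameter >= (1/2) log_a(|V| / a^f(n)), clamped at 0.

    Follows from the neighbourhood bound: radii with a^(f+2r) < |V| are
    below the diameter.  For RNNIu this reads (1/2) log_3((n-1)! n!/6^(n-1)).
    """
    a, f = _grammar_base_and_exponent(n, space)
    total = count_trees(n, space)
    bound = 0.5 * (math.log(total, a) - f)
    return max(bound, 0.0)
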