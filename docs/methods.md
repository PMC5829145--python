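# Methods

## The model

A *discrete time-tree* is a rooted binary tree on a fixed set of `n`
labelled leaves in which every node carries a distinct non-negative
integer time, parent strictly older than child.  The *rank* of a node is
the number of nodes with strictly smaller time; an *event interval* is
the gap between two rank-consecutive nodes and its *length* is their time
difference.  Two trees are identified when a leaf-label-preserving
isomorphism matches them with equal ranks and equal interval lengths, so
absolute times are irrelevant: a tree is exactly a ranked sequence of
clades plus a vector of interval lengths.  That clade sequence — the
descendant taxon set of each node, listed from the most recent node to
the root — is unique per isomorphism class and is the representation the
package stores (internally as bitmasks over the sorted label tuple).
Tree equality, hashing, graph vertices and file formats all operate on
it directly.

Five graph families arise by forgetting parts of this structure:

| family   | ranked nodes         | interval lengths | intervals |
|----------|----------------------|------------------|-----------|
| `NNI`    | none (topology only) | none             | —         |
| `RNNI`   | all `2n-1` nodes     | all 1            | `2n-2`    |
| `RNNIu`  | `n-1` internal nodes (leaves at time 0) | all 1 | `n-1` |
| `DtT_m`  | all `2n-1` nodes     | in `{1..m}`      | `2n-2`    |
| `DtTu_m` | `n-1` internal nodes | in `{1..m}`      | `n-1`     |

`RNNI`/`RNNIu` are the `m = 1` members of `DtT`/`DtTu`.  The ultrametric
convention (leaves exempt from the all-distinct-times rule, pinned to
time 0) resolves the tie among simultaneously sampled leaves; only the
internal nodes are ranked there, which also fixes the interval count at
`n-1`.

Two trees are adjacent when one primitive move converts one into the
other:

* **length move** — one interval length changes by 1 (DtT families);
* **rank swap** — the two nodes bounding a *unit* interval exchange
  ranks, allowed exactly when they are not joined by a tree edge;
* **NNI move** — on a unit interval whose endpoints are joined by an
  edge with both endpoints internal: the interval is contracted and the
  resulting degree-4 node re-resolved to either of the two other binary
  configurations; the fresh interval has length 1 and all other lengths
  are untouched.

On the clade sequence these are single-coordinate edits: a length move
touches one length, a rank swap transposes two consecutive clades, an
NNI replaces the lower clade `A` with `(A \ k) ∪ W` where `k` is one
child of `A` and `W` the sibling subtree.  Because the three edit types
touch disjoint coordinates, distinct applicable moves always give
distinct neighbours, so `degree(T) = |applicable_moves(T)|`; the test
suite re-derives this by exhaustive neighbour generation at small `n`.
Intervals are indexed by the rank of their lower endpoint and indices
are recomputed after every move.  The two NNI variants are labelled by
which child of the lower node is displaced (variant A displaces the
child containing the smallest taxon), which makes move logs replayable.

The degree envelope per family, verified tight against enumeration at
`n = 4, 5` in every family:

* `NNI`: constant `2(n-2)`;
* `RNNI`: `n-1` (taxa alternating with divergences) to `3n-4`
  (caterpillar with all taxa below all divergences);
* `RNNIu`: `n-1` (two alternating branches) to `2(n-2)` (caterpillar);
* `DtT_m`: `2n-2` (every interval at length `m`) to `5n-6`;
* `DtTu_m`: `n-1` to `3n-5`.

## Newick dialect

Input/output uses standard Newick augmented with `[&time=<int>]` node
comments (parsed via dendropy's comment-metadata extraction).  The
writer always emits every node's time plus branch lengths equal to time
differences.  The parser accepts, in order of preference: explicit time
comments; branch lengths (times reconstructed by depth, lowest node at
0); or, for plain topology strings, topological height above the leaves
— which must then rank the internal nodes strictly (caterpillar-like
inputs), otherwise the parse is rejected as ambiguous.  In the rank-only
families any strictly ranked times are accepted and lengths are
normalised to 1; in DtT families the reconstructed gaps must lie in
`[1, m]`.

## Exact graphs and guards

For small `n` whole graphs are built outright: ranked ultrametric trees
are enumerated as coalescent merge sequences (choose an unordered pair
of lineages at each step — a bijection with ranked topologies), ranked
tip-dated trees interleave leaf-sampling events with merges, DtT spaces
cross these with all length vectors, and NNI deduplicates topologies.
Closed-form counts — `(2n-3)!!` for NNI, `n!(n-1)!/2^(n-1)` for RNNIu, a
rank-sequence recursion for RNNI, times `m` per interval for DtT — are
cross-checked against these enumerations rather than trusted.

Guard rails are expressed as a maximum vertex count (default 300,000,
always overridable) rather than a leaf-count cut-off, because the
families grow at wildly different rates (RNNIu reaches 56,700 vertices
at `n = 7` while DtT_2 already has 15.2M at `n = 5`).  Shortest-path
queries that do not need the whole graph use bidirectional BFS over
on-the-fly neighbourhoods with an expansion guard.  Whole-graph distance
matrices, eccentricities and truncated balls run through
`scipy.sparse.csgraph` on a CSR adjacency.

Neighbourhood growth obeys `|B_r| ≤ a^(f(n)+2r)` with `a = 3` for the
rank-only families and `a = 4` once lengths join the move alphabet, and
`f(n)` the number of ranked nodes (`n-1` ultrametric, `2n-1` tip-dated).
This gives the diameter lower bound `½ log_a(|V|/a^f(n))` (clamped at
zero).  No such closed form is implemented for plain NNI, where the
corresponding operations refuse.

## Constructive paths in RNNIu

`construct_path` produces an explicit, deterministic, not-necessarily-
shortest walk between two ranked ultrametric trees by settling the
target's clades in rank order.  For target rank `k` it locates the most
recent common ancestor of the target clade in the running tree and
drives it down one rank at a time: a rank swap when the node below is
not its child, otherwise the unique NNI move that keeps the target taxon
set together.  An invariant argument on the shared forest below rank `k`
shows each stage ends with exactly the target clade at rank `k` and
never disturbs settled ranks, so stage `k` costs at most `n-1-k` moves
and the whole path at most `(n-1)(n-2)/2` — strictly below the diameter
upper bound `n² - 3n - 5/8` for every `n ≥ 4`.  This walk was chosen
over a quarter-partition merge recursion (move the taxa that must cross
the root as sorted caterpillars, recurse on the rest): the merge
argument counts moves but does not determine them at move level, and
its uniform-quarter assumption degenerates at small and non-aligned
`n`, whereas the greedy walk needs no base case and satisfies the same
bound.  On all pairs at `n = 4, 5` the constructed paths happen to be
exactly shortest; the package only claims validity and the bound.

`sort_to_caterpillar` reuses the same engine towards an explicit target:
the tree induced on the untouched leaves keeps its relative ranked
shape at the bottom, and the chosen leaves are attached above it in
order, so the endpoint restricted to the chosen subset is a caterpillar
with the first leaf innermost.  `validate_path` checks consecutive
adjacency (O(n) structural predicate, itself validated exhaustively
against neighbour enumeration at small `n`) and optionally replays the
move log; mass sweeps disable the replay after it has been established
on the exhaustive small-`n` instances.

## Property verifiers

**Split preservation.**  The partition of leaves given by an edge of a
rooted tree is identified by the clade below the edge (singletons and
the full set occur everywhere and are ignored).  For every clade shared
by two trees, the checker asks whether every tree on every shortest path
between them contains it.  Rather than enumerating paths, it uses a
first-exit-edge criterion: a shortest path between members of the
clade-carrying set `H` leaves `H` iff there are members `t, u` and a
non-member neighbour `v` of `u` with `d(t,v) < d(t,u)`; this is
equivalent to testing membership of every vertex of the shortest-path
DAG and needs only per-member BFS plus a vectorised scan of the boundary
edges.  The finder operates on arbitrary graphs and is itself validated
on a synthetic square graph with a planted violation.  Because label
permutations are automorphisms of every family, one representative
clade per size class suffices; tests cross-check against the exhaustive
split set at small `n`.  Result: the property holds exhaustively at
`n ≤ 5` in RNNIu and RNNI (and in the other families at the sizes the
suite enumerates), consistent with the conjecture that ranked spaces,
unlike plain NNI at large `n`, preserve shared splits.

**Closer neighbours.**  For all ordered pairs `(x, y)` the number of
neighbours `u` of `x` with `d(u,y) ≤ d(x,y)` is compared against
`3·d(x,y)` in the rank-only families, `4·d(x,y)` at `m = 2` and
`5·d(x,y)` for `m > 2`.  The bound is conditional on split preservation,
so excesses are recorded as counterexample evidence in the report, never
raised as errors.

**Caterpillar convexity.**  The fixed-form caterpillars (smallest leaf
innermost, largest outermost, `(n-2)!` of them) are checked pairwise for
a within-set shortest path by comparing the BFS distance inside the
induced subgraph with the unrestricted distance.  At `n = 7` the
two printed ladder trees are 6 apart in RNNIu with an all-caterpillar
witness, while their topologies are only 5 apart in NNI — the shorter
NNI walk bundles two leaves into a travelling cherry and must leave the
caterpillar set.

**Symmetries.**  Brute-force sweeps over all `n!` leaf permutations show
that an ultrametric ranked tree is fixed exactly by the products of its
disjoint cherry transpositions (a group of order `2^#cherries`), and a
tip-dated tree by the identity alone, since the two taxa of a cherry
occupy distinct ranks.  In particular no transposition of a non-cherry
pair ever fixes a ranked tree, which is what makes tanglegram-style
symmetry reduction unnecessary in these spaces.  The commonly quoted
"identity or one cherry transposition" phrasing misses the simultaneous
swaps: the balanced ranked 4-leaf tree is already fixed by swapping both
of its cherries at once.

## Random generation

Ranked ultrametric topologies are sampled uniformly by the backwards
coalescent (uniform pair merged at each step).  Tip-dated trees extend
the draw with a leaf-rank interleaving sampled uniformly among the
linear extensions of the node order, by exact dynamic-programming counts
over (internal nodes remaining, freed leaves).  DtT lengths are i.i.d.
uniform on `{1..m}`.  All draws flow from one seeded `random.Random`, so
outputs are byte-identical per seed.  The generator samples uniform
combinatorial objects: it emulates no clock model, no posterior mass
concentration and no data-driven shape bias, so tests built on it probe
combinatorial correctness, not inference behaviour on real data.

## Problem sizes in the test suite

Exhaustive sweeps use the whole spaces at `n ≤ 5` (RNNIu up to `n = 6`
for path validation and diameters, `n = 7` for the printed ladder pair;
DtT_2 full enumeration up to `n = 4`, with degree extremes at `n = 5`
obtained exactly by factorising the length dimension out of the 59,520
ranked shapes).  Constructive paths are additionally validated on 100
seeded pairs at each of `n = 8, 12, 16`.  These sizes keep every oracle
exact; nothing in the suite is sampled where the claim says "all".

## Known limitations

* Exact operations refuse, rather than approximate, beyond the vertex
  guard; there are no heuristic distance estimates for large `n`.
* The NNI family is carried as the rank-free floor of the hierarchy:
  moves, graphs and distances work, but the grammar-based neighbourhood
  and diameter bounds are not provided for it.
* No SPR-type moves, no multifurcating intermediates as first-class
  states, no sampled-ancestor nodes, and no continuous (real-valued)
  time geometry.
* `construct_path` is specified for RNNIu; adapting it to the lengthed
  families would need length-aware settling and is out of scope.
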