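# dtgraph — discrete time-tree graphs

Phylogenetic *time-trees* carry divergence dates on internal nodes and
sampling dates on leaves, and Bayesian samplers walk over them with
moves that respect that timing.  `dtgraph` implements the discrete
spaces underlying such walks: graphs whose vertices are trees with
integer node times and whose edges are single primitive moves.  It is a
library (plus a small CLI) for researchers studying the combinatorics
and geometry of these spaces — neighbourhood sizes, diameters, shortest
paths, convexity — and for anyone who needs exact small-`n` oracles to
test tree-proposal machinery against.

## The hierarchy

With `n` leaves fixed, five families of graphs are supported:

* **NNI** — unranked rooted topologies under nearest-neighbour
  interchange; the rank-free floor of the hierarchy.
* **RNNI / RNNIu** — ranked (resp. ranked ultrametric) trees: every
  node (resp. every internal node, leaves pinned at time 0) has a
  distinct rank.  Adjacent trees differ by one NNI move on a unit
  interval or one rank swap of rank-consecutive, non-adjacent nodes.
* **DtT_m / DtTu_m** (`m ≥ 2`) — discrete time-trees whose event
  intervals (gaps between rank-consecutive nodes) carry integer lengths
  in `{1..m}`; length-change moves join the repertoire.

A tree is stored as its unique canonical form: the sequence of clades in
rank order plus interval lengths.  Key exact quantities, for graph
`G` on `n` leaves: the vertex count `|G|` (e.g. `n!(n-1)!/2^(n-1)` for
RNNIu, `(2n-3)!!` for NNI), the degree envelope (e.g. `n-1 ≤ deg(T) ≤
2(n-2)` in RNNIu, constant `2(n-2)` in NNI, up to `5n-6` in DtT_m), the
`r`-neighbourhood bound `δ_r(G) ≤ a^{f(n)+2r}` (`a = 3` ranked, `4`
lengthed; `f(n)` the number of ranked nodes), and the diameter sandwich
`½·log_a(|G|/a^{f(n)}) ≤ Δ(G) ≤ n² − 3n − 5/8` (the upper bound for
RNNIu, `n ≥ 4`, with a constructive path algorithm behind it).

## Worked example

```python
>>> from dtgraph import (SpaceSpec, parse_tree, canonical_key,
...                      bfs_distance, construct_path, build_graph, diameter)
>>> space = SpaceSpec.rnniu()
>>> t = parse_tree("((((((1,2),3),4),5),6),7);", space)   # ladder tree
>>> r = parse_tree("((((((1,4),5),6),2),3),7);", space)   # leaves 2,3 moved up
>>> canonical_key(t)
'1,2|1,2,3|1,2,3,4|1,2,3,4,5|1,2,3,4,5,6|1,2,3,4,5,6,7'
>>> bfs_distance(t, r)                # exact, bidirectional BFS
6
>>> construct_path(t, r).length      # constructive walk attains it here
6
>>> g = build_graph(5, space)        # the whole space at n=5
>>> g.vertex_count, g.edge_count, diameter(g)
(180, 465, 6)
```

The distance 6 is what ranked timing adds to the picture: the parents of
leaves 2 and 3 ride up the ladder independently (six rank-respecting NNI
moves, all intermediate trees still ladders), whereas the same pair of
*topologies* is only 5 NNI moves apart — the unranked shortcut first
bundles 2 and 3 into a cherry, moves the cherry, and unbundles it,
leaving the ladder set.  Convexity of caterpillars separates the ranked
from the unranked spaces.

The same machinery answers degree questions (`neighbors`, `degree`,
`degree_bounds`), counts spaces (`count_trees`), checks structural
properties over entire graphs (`dtgraph.properties`: split preservation
on all shortest paths, closer-neighbour envelopes, caterpillar
convexity, degree tightness) and draws seeded uniform ranked trees
(`random_tree`).

From the shell:

```sh
$ dtgraph count --n 4 --space rnniu
18
$ dtgraph random-tree --n 5 --space dttu --m 2 --seed 7
$ dtgraph verify degrees --n 4 --space nni
{"counterexamples": [], "details": {"bounds": [4, 4], "count": 15, "degree_max": 4,
 "degree_min": 4, "extremal_degrees": {"caterpillar": 4}}, "instances_checked": 15,
 "n": 4, "property": "degree_and_count_tightness", "space": "nni", "verdict": "holds"}
```

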