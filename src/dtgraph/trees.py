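"""Tree data model for discrete time-tree graphs.

A discrete time-tree is a rooted binary tree on a fixed label set whose
nodes carry distinct integer times, parent strictly older than child.  Two
such trees are identified when they are isomorphic as leaf-labelled trees
by an isomorphism that preserves node ranks and event-interval lengths, so
a tree is fully described by

* the sequence of its clades (descendant taxon sets) listed in rank order,
  and
* the sequence of event-interval lengths (gaps between rank-consecutive
  nodes).

That clade sequence is the canonical representation used throughout this
package: equality of trees is literal equality of sequences, which makes
dictionary-based graph construction trivial.

Internally clades are stored as integer bitmasks over the sorted label
tuple; the public :class:`CladeSequence` view uses label tuples.

Conventions by family
---------------------
* ultrametric families (RNNIu, DtTu_m): all leaves sit at time 0; only the
  n-1 internal nodes are ranked (1..n-1).  ``clades`` holds the n-1
  internal clades, ``lengths`` the n-1 event intervals, interval ``i``
  separating rank ``i`` from rank ``i+1`` (rank 0 being the leaf level).
* tip-dated families (RNNI, DtT_m): all 2n-1 nodes are ranked 0..2n-2;
  ``clades`` includes the singleton leaf clades, ``lengths`` has 2n-2
  entries.
* NNI: ranking is ignored; ``clades`` holds the internal clades in a
  canonical (size, lexicographic) order and ``lengths`` is empty.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy

from .space import Family, SpaceSpec

__all__ = [
    "TreeError",
    "DiscreteTimeTree",
    "CladeSequence",
    "parse_tree",
    "write_tree",
    "canonical_representation",
    "trees_equal",
    "permute_leaves",
    "symmetry_group_check",
    "expected_symmetries",
    "cherries",
    "caterpillar_tree",
    "alternating_caterpillar",
    "low_degree_tree",
    "max_length_tree",
]


class TreeError(ValueError):
    """Invalid tree: malformed input or violated structural invariant."""


# ---------------------------------------------------------------------------
# bitmask helpers
# ---------------------------------------------------------------------------


def _labels_to_mask(labels: Sequence[str], clade: Iterable[str]) -> int:
    index = {lab: i for i, lab in enumerate(labels)}
    mask = 0
    for lab in clade:
        try:
            bit = index[lab]
        except KeyError:
            raise TreeError(f"unknown taxon {lab!r}") from None
        if mask >> bit & 1:
            raise TreeError(f"duplicate taxon {lab!r} in clade")
        mask |= 1 << bit
    return mask


def _mask_to_labels(labels: Sequence[str], mask: int) -> tuple[str, ...]:
    return tuple(lab for i, lab in enumerate(labels) if mask >> i & 1)


def _popcount(mask: int) -> int:
    return mask.bit_count()


# ---------------------------------------------------------------------------
# the tree type
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiscreteTimeTree:
    """A discrete time-tree in canonical clade-sequence form.

    Instances are immutable and hashable; two trees compare equal exactly
    when they are isomorphic in the rank- and length-preserving sense, so
    they can be used directly as dictionary keys when building graphs.
    Use :meth:`from_clades` (which validates) rather than the raw
    constructor.
    """

    labels: tuple[str, ...]
    clades: tuple[int, ...]
    lengths: tuple[int, ...]
    space: SpaceSpec

    # -- construction --------------------------------------------------

    @classmethod
    def from_clades(
        cls,
        space: SpaceSpec,
        clades: Sequence[Iterable[str]],
        lengths: Sequence[int] | None = None,
        labels: Sequence[str] | None = None,
    ) -> "DiscreteTimeTree":
        """Build and validate a tree from clades given as label collections.

        ``clades`` are listed in rank order (see module docstring for which
        nodes appear per family).  ``labels`` defaults to the union of all
        clades; ``lengths`` defaults to all 1 (and must be omitted for NNI).
        For the NNI family the given order is irrelevant and is replaced by
        the canonical (size, lexicographic) order.
        """
        clade_sets = [tuple(c) for c in clades]
        if labels is None:
            seen: set[str] = set()
            for c in clade_sets:
                seen.update(c)
            labels = sorted(seen)
        labels = tuple(sorted(labels))
        if len(set(labels)) != len(labels):
            raise TreeError("leaf labels are not distinct")
        masks = tuple(_labels_to_mask(labels, c) for c in clade_sets)
        if space.family is Family.NNI:
            if lengths not in (None, (), []):
                raise TreeError("NNI trees carry no interval lengths")
            masks = tuple(sorted(masks, key=lambda m: (_popcount(m), m)))
            lengths = ()
        elif lengths is None:
            lengths = (1,) * space.n_intervals(len(labels))
        tree = cls(labels, masks, tuple(int(x) for x in lengths), space)
        tree.validate()
        return tree

    # -- basic structure ----------------------------------------------

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def full_mask(self) -> int:
        return (1 << self.n) - 1

    def validate(self) -> None:
        """Raise :class:`TreeError` unless every invariant holds."""
        n = self.n
        if n < 2:
            raise TreeError("trees need at least two leaves")
        space = self.space
        if space.family is Family.NNI:
            expected_len = 0
        else:
            expected_len = space.n_intervals(n)
        if len(self.lengths) != expected_len:
            raise TreeError(
                f"expected {expected_len} interval lengths, got {len(self.lengths)}"
            )
        for x in self.lengths:
            if not 1 <= x <= space.m:
                raise TreeError(f"interval length {x} outside [1, {space.m}]")

        ultra_like = space.is_ultrametric or space.family is Family.NNI
        if ultra_like:
            if len(self.clades) != n - 1:
                raise TreeError(f"expected {n - 1} internal clades, got {len(self.clades)}")
            # leaves are available from the start
            roots = {1 << i for i in range(n)}
        else:
            if len(self.clades) != 2 * n - 1:
                raise TreeError(f"expected {2 * n - 1} ranked nodes, got {len(self.clades)}")
            roots = set()
        singles_seen = 0
        for pos, c in enumerate(self.clades):
            if c == 0:
                raise TreeError("empty clade")
            if _popcount(c) == 1:
                if ultra_like:
                    raise TreeError("singleton clade in ultrametric/NNI sequence")
                if c in roots:
                    raise TreeError("duplicate leaf in sequence")
                roots.add(c)
                singles_seen += 1
                continue
            kids = [r for r in roots if r & c == r]
            if len(kids) != 2 or kids[0] | kids[1] != c:
                raise TreeError(
                    f"clade at rank position {pos} is not the union of two"
                    " current subtrees (non-binary or ill-ordered sequence)"
                )
            roots.difference_update(kids)
            roots.add(c)
        if not ultra_like and singles_seen != n:
            raise TreeError("every leaf must appear exactly once in a ranked sequence")
        if roots != {self.full_mask}:
            raise TreeError("sequence does not resolve to a single root on all taxa")
        if space.family is Family.NNI:
            canon = tuple(sorted(self.clades, key=lambda m: (_popcount(m), m)))
            if self.clades != canon:
                raise TreeError("NNI clades not in canonical (size, lex) order")

    def children_masks(self, pos: int) -> tuple[int, ...]:
        """Masks of the children of the node at sequence position ``pos``.

        Singleton children (ultrametric/NNI leaves) are returned as 1-bit
        masks.  Children are ordered by smallest contained taxon.
        """
        c = self.clades[pos]
        rem = c
        kids = []
        for q in range(pos - 1, -1, -1):
            m = self.clades[q]
            if m & rem == m:
                kids.append(m)
                rem &= ~m
                if rem == 0:
                    break
        # leftover bits are leaf children (ultrametric / NNI storage)
        while rem:
            low = rem & -rem
            kids.append(low)
            rem &= ~low
        kids.sort(key=lambda m: m & -m)
        return tuple(kids)

    def parent_pos(self, pos: int) -> int | None:
        """Sequence position of the parent of node ``pos`` (None for root)."""
        c = self.clades[pos]
        for q in range(pos + 1, len(self.clades)):
            if self.clades[q] & c == c:
                return q
        return None

    def node_times(self) -> tuple[int, ...]:
        """Absolute times of the ranked nodes, lowest node at time 0.

        Ultrametric: entry ``i`` is the time of the rank ``i+1`` internal
        node (leaves sit at 0).  Tip-dated: entry ``r`` is the time of the
        rank ``r`` node.  Undefined for NNI trees.
        """
        if self.space.family is Family.NNI:
            raise TreeError("NNI trees carry no times")
        times = []
        t = 0
        for x in self.lengths:
            t += x
            times.append(t)
        if not self.space.is_ultrametric:
            # tip-dated: 2n-1 nodes, 2n-2 intervals -> the rank-0 node at 0
            times = [0] + times
        return tuple(times)

    # -- hashing / equality --------------------------------------------

    def __hash__(self) -> int:  # dataclass would include space (hashable) anyway
        return hash((self.labels, self.clades, self.lengths, self.space))


# ---------------------------------------------------------------------------
# canonical representation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CladeSequence:
    """The unique representation of a tree: clades in rank order.

    For DtT families the parallel interval lengths are included; the text
    form suffixes each clade with the length of the event interval directly
    below its node (the tip-dated rank-0 node has no interval below it and
    gets no suffix).
    """

    clades: tuple[tuple[str, ...], ...]
    lengths: tuple[int, ...] | None = None

    @property
    def text(self) -> str:
        if self.lengths is None:
            return "|".join(",".join(c) for c in self.clades)
        parts = []
        # number of clades may exceed number of intervals by one (tip-dated)
        offset = len(self.clades) - len(self.lengths)
        for i, c in enumerate(self.clades):
            body = ",".join(c)
            if i >= offset:
                body += f":{self.lengths[i - offset]}"
            parts.append(body)
        return "|".join(parts)

    def __str__(self) -> str:
        return self.text


def canonical_representation(tree: DiscreteTimeTree) -> CladeSequence:
    """Unique, deterministic representation of ``tree``.

    Two trees of the same space are isomorphic (rank- and length-preserving)
    iff their canonical representations are equal.  Taxa inside a clade are
    sorted lexicographically; clades are ordered by rank (by size then
    lexicographically for the rank-free NNI family).
    """
    clades = tuple(_mask_to_labels(tree.labels, m) for m in tree.clades)
    lengths = tree.lengths if tree.space.has_lengths else None
    return CladeSequence(clades, lengths)


def canonical_key(tree: DiscreteTimeTree) -> str:
    """Canonical text key (used for graph vertices and file formats)."""
    return canonical_representation(tree).text


def tree_from_canonical(text: str, space: SpaceSpec) -> DiscreteTimeTree:
    """Inverse of :func:`canonical_key`: rebuild a tree from its text form."""
    clades: list[tuple[str, ...]] = []
    lengths: list[int] = []
    for segment in text.split("|"):
        body, sep, suffix = segment.rpartition(":")
        if sep:
            lengths.append(int(suffix))
            clades.append(tuple(body.split(",")))
        else:
            clades.append(tuple(segment.split(",")))
    if not space.has_lengths:
        if lengths:
            raise TreeError(f"unexpected interval lengths in {space} key")
        return DiscreteTimeTree.from_clades(space, clades)
    return DiscreteTimeTree.from_clades(space, clades, lengths)


def trees_equal(t1: DiscreteTimeTree, t2: DiscreteTimeTree) -> bool:
    """Rank- and length-preserving isomorphism, as an equality test.

    Ranking is ignored for the NNI family (canonical order absorbs it);
    interval lengths are compared only in the DtT families.
    """
    if t1.labels != t2.labels:
        raise TreeError("trees are on different label sets")
    if t1.space != t2.space:
        raise TreeError(f"trees live in different spaces: {t1.space} vs {t2.space}")
    return canonical_representation(t1) == canonical_representation(t2)


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------
#
# Dialect: standard Newick augmented with per-node comments ``[&time=<int>]``.
# On output every node carries its time and branch lengths equal time
# differences.  On input, times are taken from the comments when present;
# otherwise they are reconstructed from branch lengths; otherwise (plain
# topology strings) internal-node times default to topological height above
# the leaves, which must then be strict (caterpillar-like inputs).


def _dendropy_parse(text: str):
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            extract_comment_metadata=True,
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise TreeError(f"Newick parse failure: {exc}") from exc
    return dtree


def parse_tree(text: str, space: SpaceSpec) -> DiscreteTimeTree:
    """Parse an annotated Newick string into a validated tree of ``space``."""
    dtree = _dendropy_parse(text)
    nodes = list(dtree.preorder_node_iter())
    leaves = [nd for nd in nodes if nd.is_leaf()]
    internals = [nd for nd in nodes if not nd.is_leaf()]
    for nd in internals:
        if len(nd.child_nodes()) != 2:
            raise TreeError("non-binary node in input")
    labels_list = []
    for nd in leaves:
        if nd.taxon is None or not nd.taxon.label:
            raise TreeError("unlabeled leaf in input")
        labels_list.append(str(nd.taxon.label))
    if len(set(labels_list)) != len(labels_list):
        raise TreeError("duplicate leaf labels")
    labels = tuple(sorted(labels_list))
    n = len(labels)
    if n < 2:
        raise TreeError("trees need at least two leaves")

    # clade mask per dendropy node
    mask_of: dict = {}
    for nd in dtree.postorder_node_iter():
        if nd.is_leaf():
            mask_of[nd] = 1 << labels.index(str(nd.taxon.label))
        else:
            m = 0
            for ch in nd.child_nodes():
                m |= mask_of[ch]
            mask_of[nd] = m

    if space.family is Family.NNI:
        clades = [_mask_to_labels(labels, mask_of[nd]) for nd in internals]
        return DiscreteTimeTree.from_clades(space, clades, labels=labels)

    times = _node_times_from_input(dtree, nodes, space)

    for nd in nodes:
        for ch in nd.child_nodes():
            if not times[ch] < times[nd]:
                raise TreeError(
                    "times violate parent > child"
                    f" ({times[ch]} under {times[nd]})"
                )

    if space.is_ultrametric:
        leaf_times = {times[nd] for nd in leaves}
        if len(leaf_times) != 1:
            raise TreeError("leaves of an ultrametric tree must share one time")
        ordered = sorted(internals, key=lambda nd: times[nd])
        tvals = [times[nd] for nd in ordered]
        if len(set(tvals)) != len(tvals):
            raise TreeError("tied internal-node times: ranking is ambiguous")
        base = leaf_times.pop()
        gaps = [tvals[0] - base] + [b - a for a, b in zip(tvals, tvals[1:])]
        clades = [_mask_to_labels(labels, mask_of[nd]) for nd in ordered]
    else:
        ordered = sorted(nodes, key=lambda nd: times[nd])
        tvals = [times[nd] for nd in ordered]
        if len(set(tvals)) != len(tvals):
            raise TreeError("tied node times: a ranked tree needs distinct times")
        gaps = [b - a for a, b in zip(tvals, tvals[1:])]
        clades = [_mask_to_labels(labels, mask_of[nd]) for nd in ordered]

    if space.has_lengths:
        lengths = gaps
        for g in gaps:
            if not 1 <= g <= space.m:
                raise TreeError(f"interval length {g} outside [1, {space.m}]")
    else:
        # RNNI / RNNIu: only the ranking matters, intervals are unit
        lengths = [1] * space.n_intervals(n)
    return DiscreteTimeTree.from_clades(space, clades, lengths, labels=labels)


def _node_times_from_input(dtree, nodes, space: SpaceSpec) -> dict:
    """Times per dendropy node from comments, branch lengths or topology."""
    annotated = {}
    for nd in nodes:
        val = nd.annotations.get_value("time", None)
        if val is not None:
            try:
                annotated[nd] = int(val)
            except ValueError:
                raise TreeError(f"non-integer time annotation {val!r}") from None
            if annotated[nd] < 0:
                raise TreeError("negative time annotation")
    if annotated:
        missing = [nd for nd in nodes if nd not in annotated]
        if space.is_ultrametric:
            # leaf times may be omitted; they default to 0
            for nd in missing:
                if not nd.is_leaf():
                    raise TreeError("time annotations must cover all internal nodes")
                annotated[nd] = 0
        elif missing:
            raise TreeError("time annotations must cover every node")
        return annotated

    has_bl = all(nd.edge.length is not None for nd in nodes if nd.parent_node)
    if has_bl and any(nd.parent_node for nd in nodes):
        depth = {}
        for nd in nodes:  # preorder
            depth[nd] = 0.0 if nd.parent_node is None else depth[nd.parent_node] + nd.edge.length
        height = max(depth.values())
        times = {}
        for nd in nodes:
            t = height - depth[nd]
            if abs(t - round(t)) > 1e-9:
                raise TreeError("branch lengths do not induce integer times")
            times[nd] = int(round(t))
        return times

    # plain topology: internal times default to topological height
    times = {}
    for nd in dtree.postorder_node_iter():
        if nd.is_leaf():
            times[nd] = 0
        else:
            times[nd] = 1 + max(times[ch] for ch in nd.child_nodes())
    return times


def write_tree(tree: DiscreteTimeTree) -> str:
    """Serialise to the annotated Newick dialect (round-trips via parse).

    NNI trees are written as plain topology; ranked trees carry a
    ``[&time=t]`` comment on every node and branch lengths equal to time
    differences.  Children are ordered by smallest taxon label.
    """
    if tree.space.family is Family.NNI:
        def render_nni(mask: int, pos_of: dict) -> str:
            if _popcount(mask) == 1:
                return _mask_to_labels(tree.labels, mask)[0]
            kids = tree.children_masks(pos_of[mask])
            return "(" + ",".join(render_nni(k, pos_of) for k in kids) + ")"

        pos_of = {m: i for i, m in enumerate(tree.clades)}
        return render_nni(tree.full_mask, pos_of) + ";"

    times = tree.node_times()
    pos_of = {m: i for i, m in enumerate(tree.clades)}

    def time_of(mask: int) -> int:
        if _popcount(mask) == 1 and tree.space.is_ultrametric:
            return 0
        idx = pos_of[mask]
        return times[idx]

    def render(mask: int, parent_time: int | None) -> str:
        t = time_of(mask)
        if _popcount(mask) == 1:
            body = _mask_to_labels(tree.labels, mask)[0]
        else:
            kids = tree.children_masks(pos_of[mask])
            body = "(" + ",".join(render(k, t) for k in kids) + ")"
        body += f"[&time={t}]"
        if parent_time is not None:
            body += f":{parent_time - t}"
        return body

    return render(tree.full_mask, None) + ";"


# ---------------------------------------------------------------------------
# leaf permutations and symmetries
# ---------------------------------------------------------------------------


def _permutation_table(labels: Sequence[str], sigma: Mapping[str, str]) -> list[int]:
    """bit i -> bit of sigma(labels[i]); validates bijectivity."""
    if set(sigma.keys()) != set(labels) or set(sigma.values()) != set(labels):
        raise TreeError("sigma is not a bijection on the label set")
    index = {lab: i for i, lab in enumerate(labels)}
    return [index[sigma[lab]] for lab in labels]


def _apply_table(mask: int, table: Sequence[int]) -> int:
    out = 0
    i = 0
    while mask:
        if mask & 1:
            out |= 1 << table[i]
        mask >>= 1
        i += 1
    return out


def permute_leaves(tree: DiscreteTimeTree, sigma: Mapping[str, str]) -> DiscreteTimeTree:
    """Relabel taxa by the bijection ``sigma``; ranks and lengths unchanged."""
    table = _permutation_table(tree.labels, sigma)
    masks = tuple(_apply_table(m, table) for m in tree.clades)
    if tree.space.family is Family.NNI:
        masks = tuple(sorted(masks, key=lambda m: (_popcount(m), m)))
    return DiscreteTimeTree(tree.labels, masks, tree.lengths, tree.space)


def cherries(tree: DiscreteTimeTree) -> tuple[tuple[str, str], ...]:
    """Pairs of taxa that share a parent (size-2 clades)."""
    out = []
    for m in tree.clades:
        if _popcount(m) == 2:
            a, b = _mask_to_labels(tree.labels, m)
            out.append((a, b))
    return tuple(out)


def symmetry_group_check(tree: DiscreteTimeTree, max_n: int = 8) -> frozenset[tuple[str, ...]]:
    """Brute-force the label permutations fixing ``tree``.

    Each permutation is reported as the image tuple of ``tree.labels``.
    Intended as a small-n verifier (all n! permutations are tried).
    """
    if tree.n > max_n:
        raise TreeError(f"symmetry check is exhaustive; refusing n > {max_n}")
    fixing = []
    for images in itertools.permutations(tree.labels):
        sigma = dict(zip(tree.labels, images))
        if trees_equal(tree, permute_leaves(tree, sigma)):
            fixing.append(images)
    return frozenset(fixing)


def expected_symmetries(tree: DiscreteTimeTree) -> frozenset[tuple[str, ...]]:
    """Predicted fixing permutations of a ranked tree.

    In ultrametric families both taxa of a cherry sit at time 0, so
    transposing them preserves the tree, and so does swapping any subset
    of the (pairwise disjoint) cherries simultaneously: the stabiliser is
    the group generated by the cherry transpositions, of order 2^#cherries.
    In tip-dated families the two taxa of a cherry occupy distinct ranks,
    so no non-identity permutation fixes the tree at all.  Unranked (NNI)
    trees carry larger subtree symmetries and are not covered here.
    """
    if tree.space.family is Family.NNI:
        raise TreeError("symmetry prediction applies to ranked families only")
    identity = tuple(tree.labels)
    out = {identity}
    if tree.space.is_ultrametric:
        pairs = cherries(tree)
        for r in range(1, len(pairs) + 1):
            for chosen in itertools.combinations(pairs, r):
                sigma = dict(zip(tree.labels, tree.labels))
                for a, b in chosen:
                    sigma[a], sigma[b] = b, a
                out.add(tuple(sigma[lab] for lab in tree.labels))
    return frozenset(out)


# ---------------------------------------------------------------------------
# named constructions
# ---------------------------------------------------------------------------


def caterpillar_tree(
    space: SpaceSpec,
    order: Sequence[str],
    lengths: Sequence[int] | None = None,
) -> DiscreteTimeTree:
    """Caterpillar (ladder) tree: ``order[0]`` innermost, ``order[-1]`` last.

    Internal clades are the prefixes of ``order``.  In tip-dated families
    the taxa take ranks 0..n-1 in ``order`` and the internal nodes ranks
    n..2n-2 (the short-interval caterpillar of the degree analysis).
    """
    order = list(order)
    n = len(order)
    prefixes = [tuple(order[: k + 1]) for k in range(1, n)]
    if space.family is Family.NNI or space.is_ultrametric:
        clades: list = prefixes
    else:
        clades = [(lab,) for lab in order] + prefixes
    return DiscreteTimeTree.from_clades(space, clades, lengths, labels=order)


def alternating_caterpillar(space: SpaceSpec, order: Sequence[str]) -> DiscreteTimeTree:
    """Tip-dated caterpillar with taxa ranks 0,1,3,5,... interleaving nodes.

    Divergences alternate with taxa from the present backwards: taxon,
    taxon, coalescence, taxon, coalescence, ...  This is the minimum-degree
    construction in RNNI.
    """
    if not space.is_ranked or space.is_ultrametric:
        raise TreeError("alternating caterpillar is a tip-dated construction")
    order = list(order)
    seq: list[tuple[str, ...]] = [(order[0],), (order[1],)]
    for k in range(2, len(order) + 1):
        seq.append(tuple(order[:k]))
        if k < len(order):
            seq.append((order[k],))
    return DiscreteTimeTree.from_clades(space, seq, labels=order)


def low_degree_tree(space: SpaceSpec, labels: Sequence[str]) -> DiscreteTimeTree:
    """Ultrametric tree of minimum degree n-1: two alternating branches.

    Consecutive internal nodes are never parent and child except at the
    root, so every non-root interval admits only a single rank swap while
    the root interval contributes its obligatory two NNI neighbours.
    """
    if not space.is_ultrametric:
        raise TreeError("low_degree_tree builds ultrametric trees")
    labs = sorted(labels)
    n = len(labs)
    if n < 3:
        raise TreeError("need n >= 3")
    if n == 3:
        clades = [tuple(labs[:2]), tuple(labs)]
        return DiscreteTimeTree.from_clades(space, clades, labels=labs)
    a, b = set(labs[:2]), set(labs[2:4])
    clades = [tuple(sorted(a)), tuple(sorted(b))]
    for k, lab in enumerate(labs[4:]):
        side = a if k % 2 == 0 else b
        side.add(lab)
        clades.append(tuple(sorted(side)))
    clades.append(tuple(labs))
    return DiscreteTimeTree.from_clades(space, clades, labels=labs)


def max_length_tree(space: SpaceSpec, labels: Sequence[str]) -> DiscreteTimeTree:
    """Caterpillar with every event interval at the maximum length m.

    Such a tree admits only length-decrease moves (one per interval), so
    its degree equals the number of event intervals: the DtT/DtTu minimum.
    """
    if not space.has_lengths:
        raise TreeError("max_length_tree needs a DtT/DtTu space")
    labs = sorted(labels)
    lengths = [space.m] * space.n_intervals(len(labs))
    return caterpillar_tree(space, labs, lengths)
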