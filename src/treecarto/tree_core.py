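"""Unrooted binary trees over labeled taxa: Newick I/O, split (bipartition)
extraction, reconstruction from compatible splits, exhaustive enumeration,
and majority-rule consensus.

Conventions used throughout the package:

* Taxa are indexed ``0..n-1``; by default indices follow the lexicographic
  order of the labels.
* A split is stored by its *canonical side*: the side of the bipartition
  that does **not** contain taxon index 0, encoded as a bitmask over taxon
  indices (bit 0 therefore always clear).
* Tree topology identity is identity of canonical split sets.
"""

from __future__ import annotations

import itertools
from collections.abc import Iterable, Iterator, Sequence
from dataclasses import dataclass

import dendropy

__all__ = [
    "TaxonMap",
    "Split",
    "NTree",
    "ConsensusTree",
    "NewickError",
    "IncompatibleSplitsError",
    "read_newick",
    "write_newick",
    "tree_to_splits",
    "splits_to_tree",
    "enumerate_trees",
    "count_trees",
    "random_tree",
    "majority_consensus",
    "resolution",
    "ENUMERATION_CAP",
]

#: Largest taxon count accepted by :func:`enumerate_trees` ((2n-5)!! growth).
ENUMERATION_CAP = 12


class NewickError(ValueError):
    """Raised for unparsable or structurally invalid Newick input."""


class IncompatibleSplitsError(ValueError):
    """Raised when a split set cannot coexist in one tree.

    Attributes
    ----------
    pair : tuple[Split, Split]
        An offending pair of mutually incompatible splits.
    """

    def __init__(self, a: "Split", b: "Split"):
        self.pair = (a, b)
        super().__init__(f"incompatible splits: {a} vs {b}")


class TaxonMap:
    """Immutable bijection between taxon labels and indices ``0..n-1``."""

    __slots__ = ("labels", "index")

    def __init__(self, labels: Sequence[str]):
        labels = tuple(str(x) for x in labels)
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate taxon labels")
        if len(labels) < 3:
            raise ValueError("need at least 3 taxa")
        self.labels = labels
        self.index = {lab: i for i, lab in enumerate(labels)}

    @classmethod
    def from_labels(cls, labels: Iterable[str]) -> "TaxonMap":
        """Build a map with labels sorted lexicographically."""
        return cls(sorted(str(x) for x in labels))

    @property
    def n(self) -> int:
        return len(self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    def __eq__(self, other) -> bool:
        return isinstance(other, TaxonMap) and self.labels == other.labels

    def __hash__(self) -> int:
        return hash(self.labels)

    def __repr__(self) -> str:
        return f"TaxonMap({list(self.labels)!r})"


@dataclass(frozen=True, order=True)
class Split:
    """A nontrivial bipartition of ``0..n-1``, canonically encoded.

    ``bits`` is the bitmask of the side not containing taxon 0; bit 0 is
    always clear and the canonical side has between 2 and n-2 members.
    """

    n: int
    bits: int

    def __post_init__(self):
        if self.bits & 1:
            raise ValueError("canonical side must not contain taxon 0")
        size = self.bits.bit_count()
        if not 2 <= size <= self.n - 2:
            raise ValueError(f"trivial or invalid split: |side|={size}, n={self.n}")
        if self.bits >> self.n:
            raise ValueError("side references taxa beyond n")

    @classmethod
    def from_indices(cls, side: Iterable[int], n: int) -> "Split":
        """Create a split from either side of the bipartition."""
        mask = 0
        for i in side:
            if not 0 <= i < n:
                raise ValueError(f"taxon index {i} out of range for n={n}")
            mask |= 1 << i
        if mask & 1:  # flip to the side without taxon 0
            mask = ((1 << n) - 1) & ~mask
        return cls(n, mask)

    @property
    def side(self) -> frozenset[int]:
        return frozenset(self.indices)

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(i for i in range(1, self.n) if self.bits >> i & 1)

    def compatible(self, other: "Split") -> bool:
        """Two splits can coexist in one tree iff one of the four
        side-intersections is empty."""
        if self.n != other.n:
            raise ValueError("splits over different taxon counts")
        a, b = self.bits, other.bits
        inter = a & b
        return inter == 0 or inter == a or inter == b

    def __repr__(self) -> str:
        return f"Split(n={self.n}, side={set(self.indices)})"


def _pairwise_compatible(splits: Iterable[Split]) -> None:
    splits = list(splits)
    for a, b in itertools.combinations(splits, 2):
        if not a.compatible(b):
            raise IncompatibleSplitsError(a, b)


class NTree:
    """An unrooted tree in which every vertex has degree 1 or 3.

    Leaves are the integers ``0..n-1`` (taxon indices); internal vertex ids
    are arbitrary integers ``>= n``. ``adj`` maps vertex -> tuple of
    neighbours.
    """

    __slots__ = ("taxa", "adj", "_splits", "_split_masks")

    def __init__(self, taxa: TaxonMap, adj: dict[int, tuple[int, ...]],
                 validate: bool = True):
        self.taxa = taxa
        self.adj = adj
        self._splits: frozenset[Split] | None = None
        self._split_masks: tuple[int, ...] | None = None
        if validate:
            self._validate()

    # -- structure ---------------------------------------------------------

    @property
    def n(self) -> int:
        return self.taxa.n

    def _validate(self) -> None:
        n = self.n
        leaves = set()
        for v, nbrs in self.adj.items():
            deg = len(nbrs)
            if deg not in (1, 3):
                raise ValueError(f"vertex {v} has degree {deg}; must be 1 or 3")
            if deg == 1:
                leaves.add(v)
            for u in nbrs:
                if v not in self.adj.get(u, ()):
                    raise ValueError("adjacency not symmetric")
        if leaves != set(range(n)):
            raise ValueError("degree-1 vertices must be exactly taxa 0..n-1")
        n_edges = sum(len(x) for x in self.adj.values()) // 2
        if n_edges != 2 * n - 3:
            raise ValueError(f"expected {2 * n - 3} edges, found {n_edges}")
        # connectivity
        seen = {0}
        stack = [0]
        while stack:
            for u in self.adj[stack.pop()]:
                if u not in seen:
                    seen.add(u)
                    stack.append(u)
        if len(seen) != len(self.adj):
            raise ValueError("tree is not connected")

    def edges(self) -> list[tuple[int, int]]:
        return [(v, u) for v, nbrs in self.adj.items() for u in nbrs if v < u]

    # -- splits ------------------------------------------------------------

    def split_masks(self) -> tuple[int, ...]:
        """Sorted canonical bitmasks of the tree's n-3 nontrivial splits."""
        if self._split_masks is None:
            n = self.n
            full = (1 << n) - 1
            # iterative post-order rooted at leaf 0: subtree mask below each edge
            below: dict[int, int] = {}
            parent = {0: -1}
            order = [0]
            stack = [0]
            while stack:
                v = stack.pop()
                for u in self.adj[v]:
                    if u != parent[v]:
                        parent[u] = v
                        order.append(u)
                        stack.append(u)
            for v in reversed(order):
                m = (1 << v) if v < n else 0
                for u in self.adj[v]:
                    if u != parent[v]:
                        m |= below[u]
                below[v] = m
            masks = []
            for v in order[1:]:
                m = below[v]
                size = m.bit_count()
                if 2 <= size <= n - 2:
                    # rooted at leaf 0 so m never contains bit 0
                    masks.append(m & full)
            masks.sort()
            self._split_masks = tuple(masks)
        return self._split_masks

    def splits(self) -> frozenset[Split]:
        if self._splits is None:
            n = self.n
            self._splits = frozenset(Split(n, m) for m in self.split_masks())
        return self._splits

    # -- identity ----------------------------------------------------------

    def __eq__(self, other) -> bool:
        return (isinstance(other, NTree) and self.taxa == other.taxa
                and self.split_masks() == other.split_masks())

    def __hash__(self) -> int:
        return hash((self.taxa, self.split_masks()))

    def newick(self) -> str:
        return write_newick(self)

    def __repr__(self) -> str:
        return f"NTree({self.newick()!r})"


@dataclass(frozen=True)
class ConsensusTree:
    """A (possibly unresolved) tree given by a compatible split set."""

    taxa: TaxonMap
    splits: frozenset[Split]

    def __post_init__(self):
        _pairwise_compatible(self.splits)

    @property
    def resolution(self) -> float:
        return resolution(self)


def resolution(c: ConsensusTree) -> float:
    """Fraction of the n-3 possible internal splits that are present.

    For n=3 there are no internal splits and the (unique) tree is taken to
    be fully resolved: the value is 1.0 by convention.
    """
    denom = c.taxa.n - 3
    if denom == 0:
        return 1.0
    return len(c.splits) / denom


# ---------------------------------------------------------------------------
# Newick I/O


def read_newick(text: str, taxa: TaxonMap | None = None) -> NTree:
    """Parse a Newick string into an :class:`NTree`.

    Branch lengths and internal node labels are discarded. A rooted binary
    input is unrooted by suppressing the degree-2 root. Raises
    :class:`NewickError` on parse failure, duplicate labels, or
    multifurcations.
    """
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  preserve_underscores=True,
                                  suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"cannot parse Newick: {exc}") from exc

    leaf_labels = []
    for leaf in dtree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon is not None else leaf.label
        if label is None:
            raise NewickError("leaf without a label")
        leaf_labels.append(str(label))
    if len(set(leaf_labels)) != len(leaf_labels):
        raise NewickError("duplicate taxon labels")
    if taxa is None:
        taxa = TaxonMap.from_labels(leaf_labels)
    elif set(leaf_labels) != set(taxa.labels):
        raise NewickError("tree labels do not match the supplied TaxonMap")
    n = taxa.n

    # build adjacency; leaves get taxon indices, internals get ids >= n
    adj: dict[int, list[int]] = {}
    ids: dict[int, int] = {}
    next_internal = n
    for node in dtree.preorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon is not None else node.label
            vid = taxa.index[str(label)]
        else:
            vid = next_internal
            next_internal += 1
        ids[id(node)] = vid
        adj[vid] = []
    for node in dtree.preorder_node_iter():
        for child in node.child_nodes():
            u, v = ids[id(node)], ids[id(child)]
            adj[u].append(v)
            adj[v].append(u)

    # suppress degree-2 vertices (the root of a rooted representation)
    for v in [v for v, nb in adj.items() if len(nb) == 2]:
        a, b = adj[v]
        adj[a] = [x if x != v else b for x in adj[a]]
        adj[b] = [x if x != v else a for x in adj[b]]
        del adj[v]

    for v, nbrs in adj.items():
        if len(nbrs) not in (1, 3):
            raise NewickError(
                f"multifurcation or invalid degree {len(nbrs)} at vertex {v}; "
                "input must be a fully resolved binary tree")
    try:
        return NTree(taxa, {v: tuple(nb) for v, nb in adj.items()})
    except ValueError as exc:
        raise NewickError(str(exc)) from exc


def write_newick(t: NTree) -> str:
    """Emit the unrooted trifurcating-root Newick form, no branch lengths.

    Deterministic: children are ordered by their minimum taxon index.
    """
    n = t.n
    if n == 3:
        return f"({','.join(t.taxa.labels)});"
    root = t.adj[0][0]  # internal neighbour of taxon 0

    def min_leaf(v: int, parent: int) -> int:
        if v < n:
            return v
        return min(min_leaf(u, v) for u in t.adj[v] if u != parent)

    def emit(v: int, parent: int) -> str:
        if v < n:
            return t.taxa.labels[v]
        kids = sorted((u for u in t.adj[v] if u != parent),
                      key=lambda u: min_leaf(u, v))
        return "(" + ",".join(emit(u, v) for u in kids) + ")"

    parts = sorted((u for u in t.adj[root]), key=lambda u: min_leaf(u, root))
    return "(" + ",".join(emit(u, root) for u in parts) + ");"


# ---------------------------------------------------------------------------
# splits <-> tree


def tree_to_splits(t: NTree) -> frozenset[Split]:
    """The tree's n-3 nontrivial splits, canonically encoded."""
    return t.splits()


def splits_to_tree(splits: Iterable[Split], taxa: TaxonMap) -> NTree:
    """Reconstruct the unique tree carrying exactly the given n-3 splits.

    Canonical sides (which never contain taxon 0) are clades of the tree
    rooted at taxon 0, so building proceeds from the smallest sides
    upward, joining previously built subclades at fresh internal nodes.
    """
    n = taxa.n
    splits = sorted(set(splits), key=lambda s: (s.bits.bit_count(), s.bits))
    if len(splits) != n - 3:
        raise ValueError(f"expected {n - 3} splits for n={n}, got {len(splits)}")
    for s in splits:
        if s.n != n:
            raise ValueError("split taxon count does not match TaxonMap")
    _pairwise_compatible(splits)

    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    next_id = n
    # cluster bitmask -> root vertex of the built subtree
    clusters: list[tuple[int, int]] = [(1 << i, i) for i in range(1, n)]
    for s in splits:
        node = next_id
        next_id += 1
        adj[node] = []
        members = []
        rest = []
        for mask, root in clusters:
            if mask & s.bits == mask:
                members.append((mask, root))
            else:
                rest.append((mask, root))
        if sum(m for m, _ in members) != s.bits or len(members) != 2:
            # cannot happen for a pairwise-compatible full split set
            raise IncompatibleSplitsError(s, s)
        for _, root in members:
            adj[node].append(root)
            adj[root].append(node)
        rest.append((s.bits, node))
        clusters = rest
    # the three remaining clades join taxon 0 at the last internal node
    top = next_id
    adj[top] = [0]
    adj[0].append(top)
    for _, root in clusters:
        adj[top].append(root)
        adj[root].append(top)
    return NTree(taxa, {v: tuple(nb) for v, nb in adj.items()})


# ---------------------------------------------------------------------------
# enumeration and random generation


def _default_taxa(n: int) -> TaxonMap:
    """Taxa labeled '1'..'n' in numeric order."""
    return TaxonMap([str(i + 1) for i in range(n)])


def count_trees(n: int) -> int:
    """(2n-5)!! — the number of unrooted binary topologies on n taxa."""
    if n < 3:
        raise ValueError("n must be >= 3")
    out = 1
    for k in range(3, 2 * n - 4, 2):
        out *= k
    return out


def _enumerate_edge_lists(n: int) -> Iterator[list[tuple[int, int]]]:
    """Yield every topology as an edge list, by deterministic leaf insertion.

    Taxon k is attached to every edge of every (k-1)-taxon tree, edges taken
    in construction order.
    """
    base = [(0, n), (1, n), (2, n)]

    def rec(k: int, edges: list[tuple[int, int]], nxt: int):
        if k == n:
            yield edges
            return
        for i in range(len(edges)):
            u, v = edges[i]
            new_edges = edges[:i] + edges[i + 1:] + [(u, nxt), (v, nxt), (k, nxt)]
            yield from rec(k + 1, new_edges, nxt + 1)

    yield from rec(3, base, n + 1)


def enumerate_trees(n: int, taxa: TaxonMap | None = None) -> Iterator[NTree]:
    """Yield every unrooted binary topology on n taxa exactly once.

    The order is deterministic (fixed leaf-insertion order), so enumeration
    indices are stable across runs. ``3 <= n <= ENUMERATION_CAP``.
    """
    if not 3 <= n <= ENUMERATION_CAP:
        raise ValueError(f"n must be in [3, {ENUMERATION_CAP}]")
    if taxa is None:
        taxa = _default_taxa(n)
    elif taxa.n != n:
        raise ValueError("TaxonMap size does not match n")
    for edges in _enumerate_edge_lists(n):
        adj: dict[int, list[int]] = {}
        for u, v in edges:
            adj.setdefault(u, []).append(v)
            adj.setdefault(v, []).append(u)
        yield NTree(taxa, {v: tuple(nb) for v, nb in adj.items()}, validate=False)


def random_tree(n: int, rng, taxa: TaxonMap | None = None) -> NTree:
    """Uniformly random topology by random sequential leaf insertion.

    ``rng`` is a :class:`numpy.random.Generator`.
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    if taxa is None:
        taxa = _default_taxa(n)
    edges = [(0, n), (1, n), (2, n)]
    nxt = n + 1
    for k in range(3, n):
        i = int(rng.integers(len(edges)))
        u, v = edges.pop(i)
        edges += [(u, nxt), (v, nxt), (k, nxt)]
        nxt += 1
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    return NTree(taxa, {v: tuple(nb) for v, nb in adj.items()}, validate=False)


# ---------------------------------------------------------------------------
# consensus


def majority_consensus(trees: Sequence[NTree]) -> ConsensusTree:
    """Splits occurring in strictly more than half of the input trees."""
    if not trees:
        raise ValueError("empty tree list")
    taxa = trees[0].taxa
    for t in trees:
        if t.taxa != taxa:
            raise ValueError("all trees must share one TaxonMap")
    counts: dict[Split, int] = {}
    for t in trees:
        for s in t.splits():
            counts[s] = counts.get(s, 0) + 1
    half = len(trees)
    kept = frozenset(s for s, c in counts.items() if 2 * c > half)
    return ConsensusTree(taxa, kept)
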