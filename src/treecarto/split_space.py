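"""Explicit split-space vectors and Robinson-Foulds distance.

Split space for n taxa has one 0/1 coordinate per possible nontrivial
bipartition; its dimension is ``2**(n-1) - n - 1``. Every fully resolved
tree has exactly n-3 coordinates equal to 1, so all trees lie on the
hypersphere of squared radius n-3.

The RF distance here is the raw symmetric-difference count (NOT halved and
not normalized): with that convention it equals the squared Euclidean
distance between the trees' split vectors, which is the geometry the
projection relies on. Many tools report half this value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tree_core import NTree, Split

__all__ = [
    "SplitIndexer",
    "SplitVector",
    "split_space_dimension",
    "split_index",
    "embed",
    "rf_distance",
]

#: Largest n for which dense vectors/indexer iteration are permitted.
DENSE_CAP = 20


def split_space_dimension(n: int) -> int:
    """2^(n-1) - n - 1, the number of nontrivial bipartitions of n taxa."""
    if n < 3:
        raise ValueError("n must be >= 3")
    return 2 ** (n - 1) - n - 1


class SplitIndexer:
    """Bijection between splits of n taxa and ``range(dimension)``.

    Canonical-side bitmasks are ranked in increasing numeric order; the rank
    is computed arithmetically, with no lookup tables.
    """

    __slots__ = ("n", "dimension")

    def __init__(self, n: int):
        if n < 4:
            raise ValueError("split space is empty for n < 4")
        self.n = n
        self.dimension = split_space_dimension(n)

    def _rank(self, mask: int) -> int:
        """Number of valid canonical masks strictly below ``mask``."""
        n = self.n
        below = mask // 2  # even integers below mask (bit 0 is clear)
        invalid = 1 if mask > 0 else 0  # the empty mask
        for i in range(1, n):  # singleton masks
            if (1 << i) < mask:
                invalid += 1
        if ((1 << n) - 2) < mask:  # the full side 1..n-1 (size n-1)
            invalid += 1
        return below - invalid

    def index(self, s: Split) -> int:
        if s.n != self.n:
            raise ValueError("split does not belong to this indexer's n")
        return self._rank(s.bits)

    def split_at(self, i: int) -> Split:
        if not 0 <= i < self.dimension:
            raise IndexError(f"split index {i} out of range")

        def cum(m: int) -> int:  # valid masks <= m
            return self._rank(m) + (1 if self._is_valid(m) else 0)

        lo, hi = 0, (1 << self.n) - 2  # smallest even mask with cum >= i+1
        while lo < hi:
            mid = ((lo + hi) // 2) & ~1
            if cum(mid) >= i + 1:
                hi = mid
            else:
                lo = mid + 2
        return Split(self.n, lo)

    def _is_valid(self, mask: int) -> bool:
        if mask & 1 or mask >> self.n:
            return False
        return 2 <= mask.bit_count() <= self.n - 2

    def all_splits(self):
        """Yield splits in index order (requires n <= DENSE_CAP)."""
        if self.n > DENSE_CAP:
            raise ValueError(f"explicit iteration limited to n <= {DENSE_CAP}")
        for mask in range(2, 1 << self.n, 2):
            if 2 <= mask.bit_count() <= self.n - 2:
                yield Split(self.n, mask)


def split_index(s: Split, idx: SplitIndexer) -> int:
    """Stable bijective index of a split within its split space."""
    return idx.index(s)


@dataclass(frozen=True)
class SplitVector:
    """Sparse 0/1 vector in split space (the set of 1-coordinates)."""

    n: int
    ones: frozenset[int]

    @property
    def dimension(self) -> int:
        return split_space_dimension(self.n)

    @property
    def squared_norm(self) -> int:
        return len(self.ones)

    def dense(self) -> np.ndarray:
        """Explicit dense vector; only for small n (oracle use)."""
        if self.n > DENSE_CAP:
            raise ValueError(f"dense vectors limited to n <= {DENSE_CAP}")
        v = np.zeros(self.dimension)
        v[sorted(self.ones)] = 1.0
        return v


def embed(t: NTree) -> SplitVector:
    """Map a tree to its split-space vector (n-3 ones)."""
    if t.n == 3:
        return SplitVector(3, frozenset())
    idx = SplitIndexer(t.n)
    return SplitVector(t.n, frozenset(idx._rank(m) for m in t.split_masks()))


def rf_distance(a: NTree, b: NTree) -> int:
    """Symmetric-difference count of the two trees' nontrivial split sets.

    Equals the squared Euclidean distance between ``embed(a)`` and
    ``embed(b)``; 0 iff the trees are topology-equal.
    """
    if a.taxa != b.taxa:
        raise ValueError("trees must share one TaxonMap")
    sa, sb = set(a.split_masks()), set(b.split_masks())
    return len(sa ^ sb)
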