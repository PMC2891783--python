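"""Hash-table-backed cartographic projection of tree space.

A tree's split vector lies on a hypersphere in a space whose dimension is
exponential in n, so the k reference vectors of a linear projection are
never stored explicitly. Instead each reference vector j is defined through
a short *representative* vector R_j of length d and a hash function h on
serialized splits:

    reference_j[i] = R_j[ h(key(split_i)) mod d ]

Projecting a tree is then the sum, over its n-3 splits, of the k-tuples
looked up in the table — O(n) time and O(k*d) memory independent of n.

Determinism: splits are serialized with a fixed-width big-endian key and
summed in increasing canonical-mask order, so coordinates are bit-identical
across runs for a given seed and configuration.
"""

from __future__ import annotations

import struct
from collections.abc import Callable, Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .tree_core import NTree, Split, TaxonMap, enumerate_trees, splits_to_tree
from .split_space import SplitIndexer, embed

__all__ = [
    "HashScheme",
    "ReferenceVectorSet",
    "ProjectedPoint",
    "ProjectionDiagnostics",
    "jenkins_oaat",
    "modulo_sum_hash",
    "split_key",
    "build_reference_set",
    "reference_set_from_slot_table",
    "reference_set_from_split_coords",
    "toy_modulo3_reference_set",
    "reference_entry",
    "project",
    "project_batch",
    "diagnostics",
    "invert",
    "DEFAULT_TABLE_SIZE",
    "DEFAULT_DIMS",
]

DEFAULT_TABLE_SIZE = 65535
DEFAULT_DIMS = 3


# ---------------------------------------------------------------------------
# split serialization and hash functions


def split_key(s: Split) -> bytes:
    """Deterministic byte key for a split: big-endian 4-byte n, then the
    sorted canonical-side indices, 4 bytes each. Injective for fixed n."""
    return struct.pack(f">{1 + len(s.indices)}I", s.n, *s.indices)


def _unpack_key(key: bytes) -> tuple[int, tuple[int, ...]]:
    vals = struct.unpack(f">{len(key) // 4}I", key)
    return vals[0], vals[1:]


def jenkins_oaat(data: bytes) -> int:
    """Bob Jenkins' one-at-a-time hash (32-bit)."""
    h = 0
    for b in data:
        h = (h + b) & 0xFFFFFFFF
        h = (h + ((h << 10) & 0xFFFFFFFF)) & 0xFFFFFFFF
        h ^= h >> 6
    h = (h + ((h << 3) & 0xFFFFFFFF)) & 0xFFFFFFFF
    h ^= h >> 11
    h = (h + ((h << 15) & 0xFFFFFFFF)) & 0xFFFFFFFF
    return h


def modulo_sum_hash(key: bytes) -> int:
    """Toy hash: sum of the 1-based taxon numbers on the smaller side.

    Matches the printed 5-taxon example, where the two-taxon side's labels
    are summed and reduced modulo the table size. Ties in side size go to
    the side containing taxon 0.
    """
    n, side = _unpack_key(key)
    if 2 * len(side) > n or 2 * len(side) == n:
        side = tuple(i for i in range(n) if i not in side)
    return sum(i + 1 for i in side)


@dataclass(frozen=True)
class HashScheme:
    """A named deterministic hash from split keys to nonnegative ints."""

    name: str
    function: Callable[[bytes], int]

    def __call__(self, key: bytes) -> int:
        return self.function(key)


JENKINS = HashScheme("jenkins_oaat", jenkins_oaat)
MODULO_SUM = HashScheme("modulo_sum", modulo_sum_hash)

HASH_SCHEMES: dict[str, HashScheme] = {s.name: s for s in (JENKINS, MODULO_SUM)}


# ---------------------------------------------------------------------------
# reference vector sets


@dataclass
class ReferenceVectorSet:
    """k implicit reference vectors realized by a (k, d) representative
    table plus a hash scheme."""

    representatives: np.ndarray  # shape (k, d)
    scheme: HashScheme = JENKINS
    seed: int | None = None

    def __post_init__(self):
        self.representatives = np.asarray(self.representatives, dtype=float)
        if self.representatives.ndim != 2:
            raise ValueError("representatives must be a (k, d) array")

    @property
    def k(self) -> int:
        return self.representatives.shape[0]

    @property
    def d(self) -> int:
        return self.representatives.shape[1]

    def slot(self, s: Split) -> int:
        return self.scheme(split_key(s)) % self.d

    def entry(self, s: Split) -> np.ndarray:
        return self.representatives[:, self.slot(s)]


def build_reference_set(k: int = DEFAULT_DIMS, d: int = DEFAULT_TABLE_SIZE,
                        seed: int = 0,
                        scheme: HashScheme = JENKINS) -> ReferenceVectorSet:
    """Seeded uniform[-1,1] representatives, Gram-Schmidt orthogonalized and
    rescaled so every vector has the magnitude of the first."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if d < k:
        raise ValueError("table size d must be >= k (Gram-Schmidt degenerate)")
    rng = np.random.default_rng(seed)
    m = rng.uniform(-1.0, 1.0, size=(k, d))
    for j in range(k):
        for i in range(j):
            m[j] -= (m[j] @ m[i]) / (m[i] @ m[i]) * m[i]
        if not np.any(m[j]):
            raise ValueError("degenerate representatives; try another seed")
    target = np.linalg.norm(m[0])
    for j in range(1, k):
        m[j] *= target / np.linalg.norm(m[j])
    return ReferenceVectorSet(m, scheme=scheme, seed=seed)


def reference_set_from_slot_table(slots: Sequence[Sequence[float]],
                                  scheme: HashScheme) -> ReferenceVectorSet:
    """Build a set from explicit per-slot k-tuples (slot index -> vector)."""
    table = np.asarray(slots, dtype=float)  # (d, k)
    return ReferenceVectorSet(table.T.copy(), scheme=scheme)


def toy_modulo3_reference_set() -> ReferenceVectorSet:
    """The printed 5-taxon toy scheme: d=3 slots under the modulo-3
    label-sum hash, slot vectors (1.0,0.9), (-0.9,0.9), (-0.8,-0.8)."""
    return reference_set_from_slot_table(
        [(1.0, 0.9), (-0.9, 0.9), (-0.8, -0.8)], scheme=MODULO_SUM)


def reference_set_from_split_coords(
        coords: Mapping[Split, Sequence[float]]) -> ReferenceVectorSet:
    """Assign explicit per-split coordinates (a perfect one-slot-per-split
    table). Splits absent from the mapping contribute the zero vector."""
    items = sorted(coords.items(), key=lambda kv: (kv[0].n, kv[0].bits))
    k = len(next(iter(coords.values())))
    table = np.zeros((k, len(items) + 1))
    lookup = {split_key(s): i for i, (s, _) in enumerate(items)}
    for i, (_, vec) in enumerate(items):
        table[:, i] = vec
    zero_slot = len(items)
    scheme = HashScheme("split_table",
                        lambda key: lookup.get(key, zero_slot))
    return ReferenceVectorSet(table, scheme=scheme)


# ---------------------------------------------------------------------------
# projection


@dataclass(frozen=True)
class ProjectedPoint:
    """Image of a tree under the projection, optionally scored."""

    coordinates: tuple[float, ...]
    tree_id: int | str | None = None
    score: float | None = None

    def __iter__(self):
        return iter(self.coordinates)

    def __len__(self):
        return len(self.coordinates)


def reference_entry(rvs: ReferenceVectorSet, s: Split) -> np.ndarray:
    """The k table values contributed by one split (O(1) lookup)."""
    return rvs.entry(s)


def project(t: NTree, rvs: ReferenceVectorSet,
            tree_id: int | str | None = None,
            score: float | None = None) -> ProjectedPoint:
    """Sum the table entries of the tree's n-3 splits: O(n) total.

    Splits are summed in increasing canonical-mask order so the result is
    bit-reproducible.
    """
    coords = [0.0] * rvs.k
    n = t.n
    for mask in t.split_masks():  # already sorted ascending
        entry = rvs.entry(Split(n, mask))
        for j in range(rvs.k):
            coords[j] += float(entry[j])
    return ProjectedPoint(tuple(coords), tree_id=tree_id, score=score)


def project_batch(trees: Iterable[NTree], rvs: ReferenceVectorSet,
                  scores: Sequence[float] | None = None) -> list[ProjectedPoint]:
    """Order-preserving projection of a tree stream; ids are 0-based
    positions unless trees carry none."""
    out: list[ProjectedPoint] = []
    taxa: TaxonMap | None = None
    for i, t in enumerate(trees):
        if taxa is None:
            taxa = t.taxa
        elif t.taxa != taxa:
            raise ValueError("all trees must share one TaxonMap")
        score = None if scores is None else scores[i]
        out.append(project(t, rvs, tree_id=i, score=score))
    return out


# ---------------------------------------------------------------------------
# diagnostics


@dataclass
class ProjectionDiagnostics:
    """Empirical quality measures of the implicit reference vectors for a
    concrete taxon count (explicitly expanded, so small n only)."""

    n: int
    d: int
    dimension: int
    occupancy: np.ndarray          # f_i: splits hashed to each table slot
    xi: float                      # sum_i (f_i - dimension/d)^2
    pairwise_angles_deg: np.ndarray  # (k, k), degrees
    magnitude_ratios: np.ndarray   # norms relative to the first vector
    rank: int
    expanded: np.ndarray = field(repr=False)  # (k, dimension)


def diagnostics(rvs: ReferenceVectorSet, n: int) -> ProjectionDiagnostics:
    """Expand the true reference vectors for n taxa and measure their
    linear independence, orthogonality, magnitudes and hash evenness."""
    idx = SplitIndexer(n)
    dprime = idx.dimension
    slots = np.fromiter((rvs.slot(s) for s in idx.all_splits()),
                        dtype=np.int64, count=dprime)
    expanded = rvs.representatives[:, slots]
    occupancy = np.bincount(slots, minlength=rvs.d)
    xi = float(((occupancy - dprime / rvs.d) ** 2).sum())
    norms = np.linalg.norm(expanded, axis=1)
    k = rvs.k
    angles = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            denom = norms[i] * norms[j]
            cosang = (expanded[i] @ expanded[j]) / denom if denom else np.nan
            angles[i, j] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    rank = int(np.linalg.matrix_rank(expanded))
    ratios = norms / norms[0] if norms[0] else norms
    return ProjectionDiagnostics(n=n, d=rvs.d, dimension=dprime,
                                 occupancy=occupancy, xi=xi,
                                 pairwise_angles_deg=angles,
                                 magnitude_ratios=ratios, rank=rank,
                                 expanded=expanded)


# ---------------------------------------------------------------------------
# inverse lookup


def invert(p: Sequence[float], rvs: ReferenceVectorSet, taxa: TaxonMap,
           beam: int = 2000, tol: float = 1e-9,
           exhaustive: bool | None = None) -> list[NTree]:
    """Trees whose projection lies within ``tol`` (Euclidean) of ``p``.

    For n <= 7 (or ``exhaustive=True``) every topology is enumerated, so
    the answer is complete. Otherwise a beam search over compatible split
    sets is used, ranking partial split sets by the distance of their
    partial coordinate sums to the target; this is a heuristic and may miss
    solutions for narrow beams.
    """
    target = np.asarray(p, dtype=float)
    if target.shape != (rvs.k,):
        raise ValueError(f"target must have {rvs.k} coordinates")
    n = taxa.n
    if exhaustive is None:
        exhaustive = n <= 7
    hits: list[tuple[float, NTree]] = []
    if exhaustive:
        for t in enumerate_trees(n, taxa):
            pt = project(t, rvs)
            dist = float(np.linalg.norm(np.asarray(pt.coordinates) - target))
            if dist <= tol:
                hits.append((dist, t))
    else:
        if beam < 1:
            raise ValueError("beam must be >= 1")
        idx = SplitIndexer(n)
        splits = list(idx.all_splits())
        entries = [rvs.entry(s) for s in splits]
        # states: (sorted split tuple ending at position `last`, partial sum)
        states: list[tuple[tuple[int, ...], np.ndarray]] = [((), np.zeros(rvs.k))]
        for depth in range(n - 3):
            # partial sums are compared against a proportionally scaled
            # target: after depth+1 of n-3 splits, roughly that fraction of
            # the final coordinates should have accumulated
            frac = (depth + 1) / (n - 3)
            nxt: list[tuple[float, tuple[int, ...], np.ndarray]] = []
            for chosen, acc in states:
                start = chosen[-1] + 1 if chosen else 0
                for i in range(start, len(splits)):
                    if all(splits[i].compatible(splits[j]) for j in chosen):
                        acc2 = acc + entries[i]
                        d = float(np.linalg.norm(acc2 - frac * target))
                        nxt.append((d, chosen + (i,), acc2))
            nxt.sort(key=lambda x: (x[0], x[1]))
            states = [(c, a) for _, c, a in nxt[:beam]]
        for chosen, acc in states:
            dist = float(np.linalg.norm(acc - target))
            if dist <= tol:
                t = splits_to_tree([splits[i] for i in chosen], taxa)
                hits.append((dist, t))
    hits.sort(key=lambda h: (h[0], h[1].split_masks()))
    return [t for _, t in hits]
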