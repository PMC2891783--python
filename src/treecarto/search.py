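"""Parsimony scoring and tree-rearrangement search at toy scale.

Fitch small-parsimony on DNA with IUPAC ambiguity, TBR and NNI
neighbourhoods at the topology level (deduplicated by canonical split
sets), per-neighbourhood score spectra, and a steepest-descent hill climb
that records a sampled trace of the rearrangements it evaluates.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np

from .tree_core import NTree, TaxonMap

__all__ = [
    "Alignment",
    "SearchTrace",
    "IUPAC_STATES",
    "fitch_score",
    "nni_neighborhood",
    "tbr_neighborhood",
    "score_spectrum",
    "hill_climb",
]

# bitmask state sets: A=1, C=2, G=4, T=8; gaps/unknowns = any state
IUPAC_STATES: dict[str, int] = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15, "X": 15, "-": 15, "?": 15,
}

_BASE_OF_BIT = {1: "A", 2: "C", 4: "G", 8: "T"}


@dataclass(frozen=True)
class Alignment:
    """DNA alignment as per-taxon bitmask state sets.

    ``sites`` has shape (n_taxa, n_sites); row order follows ``taxa``.
    """

    taxa: TaxonMap
    sites: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.sites, dtype=np.uint8)
        if arr.ndim != 2 or arr.shape[0] != self.taxa.n:
            raise ValueError("sites must be (n_taxa, n_sites)")
        if arr.shape[1] < 1:
            raise ValueError("empty alignment")
        if np.any(arr == 0) or np.any(arr > 15):
            raise ValueError("invalid state bitmask")
        object.__setattr__(self, "sites", arr)

    @property
    def n_sites(self) -> int:
        return self.sites.shape[1]

    @classmethod
    def from_sequences(cls, seqs: Mapping[str, str],
                       taxa: TaxonMap | None = None) -> "Alignment":
        if taxa is None:
            taxa = TaxonMap.from_labels(seqs.keys())
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) != 1:
            raise ValueError("sequences must have equal length")
        mat = np.empty((taxa.n, lengths.pop()), dtype=np.uint8)
        for label, seq in seqs.items():
            row = taxa.index[label]
            for j, ch in enumerate(seq.upper()):
                try:
                    mat[row, j] = IUPAC_STATES[ch]
                except KeyError:
                    raise ValueError(f"unknown character {ch!r} in {label}")
        return cls(taxa, mat)

    @classmethod
    def from_fasta(cls, path, taxa: TaxonMap | None = None) -> "Alignment":
        seqs: dict[str, list[str]] = {}
        current = None
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    current = line[1:].split()[0]
                    if current in seqs:
                        raise ValueError(f"duplicate FASTA record {current!r}")
                    seqs[current] = []
                elif current is None:
                    raise ValueError("FASTA data before first header")
                else:
                    seqs[current].append(line)
        return cls.from_sequences({k: "".join(v) for k, v in seqs.items()},
                                  taxa=taxa)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, label in enumerate(self.taxa.labels):
                chars = []
                for b in self.sites[i]:
                    chars.append(_BASE_OF_BIT.get(int(b), "N"))
                fh.write(f">{label}\n{''.join(chars)}\n")


def fitch_score(t: NTree, a: Alignment) -> int:
    """Minimum total state changes over all sites (Fitch algorithm).

    The tree is rooted at an arbitrary internal vertex for the pass; the
    score is rooting-independent.
    """
    if t.taxa != a.taxa:
        raise ValueError("tree and alignment taxa differ")
    n = t.n
    root = t.adj[0][0]
    parent = {root: -1}
    order = [root]
    stack = [root]
    while stack:
        v = stack.pop()
        for u in t.adj[v]:
            if u != parent[v]:
                parent[u] = v
                order.append(u)
                stack.append(u)
    states: dict[int, np.ndarray] = {}
    changes = np.zeros(a.n_sites, dtype=np.int64)
    for v in reversed(order):
        if v < n:
            states[v] = a.sites[v]
            continue
        kids = [u for u in t.adj[v] if u != parent[v]]
        acc = states[kids[0]]
        for u in kids[1:]:
            inter = acc & states[u]
            union = acc | states[u]
            empty = inter == 0
            changes += empty
            acc = np.where(empty, union, inter)
        states[v] = acc
        for u in kids:
            del states[u]
    return int(changes.sum())


# ---------------------------------------------------------------------------
# rearrangement neighbourhoods


def _component(adj: dict[int, tuple[int, ...]], start: int,
               banned_edge: tuple[int, int]) -> set[int]:
    seen = {start}
    stack = [start]
    bu, bv = banned_edge
    while stack:
        v = stack.pop()
        for u in adj[v]:
            if (v, u) in ((bu, bv), (bv, bu)):
                continue
            if u not in seen:
                seen.add(u)
                stack.append(u)
    return seen


def _suppress(adj: dict[int, list[int]], v: int) -> tuple[int, int] | None:
    """Remove a degree-2 vertex, rejoining its neighbours; returns the new
    edge, or None if v is not degree 2."""
    if len(adj[v]) != 2:
        return None
    a, b = adj[v]
    adj[a] = [x if x != v else b for x in adj[a]]
    adj[b] = [x if x != v else a for x in adj[b]]
    del adj[v]
    return (a, b)


def tbr_neighborhood(t: NTree) -> set[NTree]:
    """All distinct topologies one tree-bisection-reconnection away.

    Every branch is bisected; the two fragments are rejoined by a new
    branch between every pair of their edges (a single-leaf fragment
    attaches at the leaf itself). Results are deduplicated by canonical
    split set and exclude the input topology.
    """
    n = t.n
    if n < 4:
        raise ValueError("TBR requires n >= 4")
    out: dict[tuple[int, ...], NTree] = {}
    self_key = t.split_masks()
    fresh = max(t.adj) + 1
    for (eu, ev) in t.edges():
        comp_u = _component(t.adj, eu, (eu, ev))
        comp_v = set(t.adj) - comp_u
        frag = {}
        for name, nodes, anchor in (("u", comp_u, eu), ("v", comp_v, ev)):
            adj = {v: [x for x in t.adj[v] if x in nodes] for v in nodes}
            if len(nodes) > 1:
                _suppress(adj, anchor)
            frag[name] = adj
        for e1 in _attach_points(frag["u"]):
            for e2 in _attach_points(frag["v"]):
                adj = {v: list(nb) for v, nb in frag["u"].items()}
                adj.update({v: list(nb) for v, nb in frag["v"].items()})
                p1 = _attach(adj, e1, fresh)
                p2 = _attach(adj, e2, fresh + 1)
                adj[p1].append(p2)
                adj[p2].append(p1)
                nt = NTree(t.taxa, {v: tuple(nb) for v, nb in adj.items()},
                           validate=False)
                key = nt.split_masks()
                if key != self_key:
                    out.setdefault(key, nt)
    return set(out.values())


def _attach_points(adj: dict[int, list[int]]):
    """Attachment sites of a fragment: its edges, or the lone vertex."""
    if len(adj) == 1:
        yield next(iter(adj))
        return
    for v, nbrs in adj.items():
        for u in nbrs:
            if v < u:
                yield (v, u)


def _attach(adj: dict[int, list[int]], site, new_id: int) -> int:
    """Subdivide an edge with a new vertex (or return a lone vertex)."""
    if isinstance(site, int):
        return site
    u, v = site
    adj[u] = [x if x != v else new_id for x in adj[u]]
    adj[v] = [x if x != u else new_id for x in adj[v]]
    adj[new_id] = [u, v]
    return new_id


def nni_neighborhood(t: NTree) -> set[NTree]:
    """The 2(n-3) nearest-neighbour-interchange topologies."""
    n = t.n
    if n < 4:
        raise ValueError("NNI requires n >= 4")
    out: dict[tuple[int, ...], NTree] = {}
    for (u, v) in t.edges():
        if u < n or v < n:
            continue  # internal edges only
        u_kids = [x for x in t.adj[u] if x != v]
        v_kids = [x for x in t.adj[v] if x != u]
        for swap in v_kids:
            a = u_kids[1]
            adj = {w: list(nb) for w, nb in t.adj.items()}
            adj[u] = [x if x != a else swap for x in adj[u]]
            adj[v] = [x if x != swap else a for x in adj[v]]
            adj[a] = [x if x != u else v for x in adj[a]]
            adj[swap] = [x if x != v else u for x in adj[swap]]
            nt = NTree(t.taxa, {w: tuple(nb) for w, nb in adj.items()},
                       validate=False)
            out.setdefault(nt.split_masks(), nt)
    return set(out.values())


def score_spectrum(t: NTree, a: Alignment) -> Counter:
    """Histogram (score -> count) of Fitch scores over the TBR
    neighbourhood of ``t``."""
    return Counter(fitch_score(nb, a) for nb in tbr_neighborhood(t))


# ---------------------------------------------------------------------------
# hill climbing


@dataclass
class SearchTrace:
    """Accepted path of a steepest-descent search plus a periodic sample of
    the rearrangements that were evaluated."""

    accepted: list[tuple[NTree, int]]
    sampled_rejected: list[tuple[NTree, int]]
    sampling_period: int

    @property
    def best(self) -> tuple[NTree, int]:
        return self.accepted[-1]


def hill_climb(a: Alignment, start: NTree, sampling_period: int = 100,
               seed: int = 0) -> SearchTrace:
    """Steepest-descent TBR search from ``start`` until no neighbour is
    strictly better.

    Every ``sampling_period``-th evaluated rearrangement (counted over the
    whole run) is recorded with its score. Ties among equally best
    neighbours break to the lowest canonical split encoding, so the run is
    deterministic; ``seed`` is accepted for interface uniformity.
    """
    if sampling_period < 1:
        raise ValueError("sampling_period must be >= 1")
    if a.taxa != start.taxa:
        raise ValueError("tree and alignment taxa differ")
    current = start
    cur_score = fitch_score(start, a)
    accepted = [(current, cur_score)]
    sampled: list[tuple[NTree, int]] = []
    evaluated = 0
    while True:
        best: tuple[int, tuple[int, ...], NTree] | None = None
        for nb in sorted(tbr_neighborhood(current),
                         key=lambda x: x.split_masks()):
            s = fitch_score(nb, a)
            evaluated += 1
            if evaluated % sampling_period == 0:
                sampled.append((nb, s))
            cand = (s, nb.split_masks(), nb)
            if best is None or cand[:2] < best[:2]:
                best = cand
        if best is None or best[0] >= cur_score:
            break
        cur_score, _, current = best
        accepted.append((current, cur_score))
    return SearchTrace(accepted=accepted, sampled_rejected=sampled,
                       sampling_period=sampling_period)
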