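"""Neighborhood-consensus locality experiment and MDS baselines.

For every tree of an exhaustive set, the m nearest neighbours under a given
low-dimensional placement are collected and the resolution of their
majority-rule consensus is recorded. A placement that keeps topologically
similar trees together yields well-resolved neighbourhood consensi; a star
consensus (resolution 0) means the neighbourhood is topologically random.

Placements compared: the cartographic projection (fresh random reference
vectors per replicate) and classical stress-majorization MDS of the
Robinson-Foulds distance matrix in 2 and 3 dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from scipy import stats

from .tree_core import NTree, enumerate_trees
from .split_space import SplitIndexer
from .cartographic import (ProjectedPoint, build_reference_set, project_batch,
                           DEFAULT_TABLE_SIZE, DEFAULT_DIMS)

__all__ = [
    "MDSEmbedding",
    "LocalityTable",
    "knn_neighborhood",
    "mds_embed",
    "rf_distance_matrix",
    "locality_experiment",
    "dominance_check",
    "METHODS",
]

METHODS = ("cartographic", "mds2", "mds3")


def _as_coords(points) -> np.ndarray:
    if isinstance(points, np.ndarray):
        return np.asarray(points, dtype=float)
    return np.asarray([tuple(p.coordinates) if isinstance(p, ProjectedPoint)
                       else tuple(p) for p in points], dtype=float)


def knn_neighborhood(points, focal: int, m: int) -> list[int]:
    """Indices of the focal point plus its m nearest others (Euclidean).

    Ties are broken by ascending index; the focal point is always first.
    """
    coords = _as_coords(points)
    npts = len(coords)
    if not 0 <= focal < npts:
        raise IndexError("focal index out of range")
    if not 0 <= m < npts:
        raise ValueError(f"m must be in [0, {npts - 1}]")
    d = np.linalg.norm(coords - coords[focal], axis=1)
    others = np.delete(np.arange(npts), focal)
    order = others[np.argsort(d[others], kind="stable")]
    return [focal] + order[:m].tolist()


@dataclass
class MDSEmbedding:
    """Result of iterative stress-majorization (SMACOF) MDS."""

    coordinates: np.ndarray        # (N, dims)
    stress: float                  # final raw stress sum_{i<j} (d - dhat)^2
    stresses: list[float]          # per-iteration, non-increasing
    seed: int
    converged: bool
    n_iter: int

    @property
    def dims(self) -> int:
        return self.coordinates.shape[1]


def mds_embed(dist: np.ndarray, dims: int = 3, seed: int = 0,
              max_iter: int = 300, tol: float = 1e-9) -> MDSEmbedding:
    """SMACOF with seeded random initialization.

    The Guttman transform guarantees a non-increasing stress sequence;
    iteration stops when the relative stress decrease drops below ``tol``.
    """
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T) or np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if dims not in (2, 3):
        raise ValueError("dims must be 2 or 3")
    N = D.shape[0]
    rng = np.random.default_rng(seed)
    scale = D.max() if D.max() > 0 else 1.0
    X = rng.uniform(-0.5, 0.5, size=(N, dims)) * scale
    stresses: list[float] = []
    converged = False
    for it in range(max_iter):
        E = squareform(pdist(X))
        stresses.append(float(((D - E) ** 2).sum()) / 2.0)
        if len(stresses) > 1:
            prev, cur = stresses[-2], stresses[-1]
            if prev - cur <= tol * max(prev, 1e-300):
                converged = True
                break
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(E > 0, D / E, 0.0)
        B = -ratio
        np.fill_diagonal(B, 0.0)
        np.fill_diagonal(B, -B.sum(axis=1))
        X = (B @ X) / N
    return MDSEmbedding(coordinates=X, stress=stresses[-1], stresses=stresses,
                        seed=seed, converged=converged, n_iter=len(stresses))


def rf_distance_matrix(trees: list[NTree]) -> np.ndarray:
    """Pairwise RF (symmetric-difference) distances, vectorized via the
    split incidence matrix."""
    n = trees[0].n
    idx = SplitIndexer(n)
    S = np.zeros((len(trees), idx.dimension), dtype=np.int32)
    for i, t in enumerate(trees):
        for m in t.split_masks():
            S[i, idx._rank(m)] = 1
    shared = S @ S.T
    sizes = S.sum(axis=1)
    return sizes[:, None] + sizes[None, :] - 2 * shared


@dataclass
class LocalityTable:
    """Per-(method, replicate, m) min/avg/max consensus resolution."""

    table: pd.DataFrame  # columns: method, replicate, m, min, avg, max
    n: int
    m_max: int
    replicates: int
    methods: tuple[str, ...]
    seed: int
    config: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def mean_avg(self, method: str) -> pd.Series:
        """Mean (over replicates) of the average resolution, indexed by m."""
        sub = self.table[self.table["method"] == method]
        return sub.groupby("m")["avg"].mean()


def _resolution_profile(order: np.ndarray, tree_split_ids: list[np.ndarray],
                        m_max: int, dim: int, n_internal: int) -> np.ndarray:
    """Resolution of the majority consensus of the first m+1 trees in
    ``order``, for m = 0..m_max, computed incrementally."""
    counts = np.zeros(dim, dtype=np.int64)
    out = np.empty(m_max + 1)
    for m in range(m_max + 1):
        counts[tree_split_ids[order[m]]] += 1
        out[m] = int((2 * counts > (m + 1)).sum()) / n_internal
    return out


def locality_experiment(n: int, m_max: int = 25, replicates: int = 100,
                        methods: tuple[str, ...] = METHODS, seed: int = 0,
                        k: int = DEFAULT_DIMS, d: int = DEFAULT_TABLE_SIZE,
                        mds_max_iter: int = 150,
                        max_mds_trees: int = 2000) -> LocalityTable:
    """Run the neighbourhood-consensus comparison on the exhaustive tree
    set of n taxa.

    Each replicate draws a fresh reference-vector seed (cartographic) or
    MDS initialization. If the tree set exceeds ``max_mds_trees`` the MDS
    baselines run on a seeded subsample (the RF matrix is quadratic).
    """
    if not 4 <= n <= 8:
        raise ValueError("locality experiment supports 4 <= n <= 8")
    if m_max < 0:
        raise ValueError("m_max must be >= 0")
    for meth in methods:
        if meth not in METHODS:
            raise ValueError(f"unknown method {meth!r}; choose from {METHODS}")
    trees = list(enumerate_trees(n))
    ntrees = len(trees)
    if m_max >= ntrees:
        raise ValueError("m_max must be smaller than the number of trees")
    idx = SplitIndexer(n)
    split_ids = [np.fromiter((idx._rank(m) for m in t.split_masks()),
                             dtype=np.int64) for t in trees]
    n_internal = n - 3

    ss = np.random.SeedSequence(seed)
    child_seeds = {}
    children = ss.spawn(len(METHODS) * replicates)
    for i, meth in enumerate(METHODS):
        for r in range(replicates):
            child_seeds[(meth, r)] = int(
                children[i * replicates + r].generate_state(1)[0])

    mds_needed = any(m.startswith("mds") for m in methods)
    if mds_needed:
        if ntrees > max_mds_trees:
            sub_rng = np.random.default_rng(
                int(ss.spawn(1)[0].generate_state(1)[0]))
            mds_subset = np.sort(sub_rng.choice(ntrees, size=max_mds_trees,
                                                replace=False))
        else:
            mds_subset = np.arange(ntrees)
        rf = rf_distance_matrix([trees[i] for i in mds_subset]).astype(float)
        mds_split_ids = [split_ids[i] for i in mds_subset]

    rows = []
    for meth in methods:
        for rep in range(replicates):
            rep_seed = child_seeds[(meth, rep)]
            if meth == "cartographic":
                rvs = build_reference_set(k=k, d=d, seed=rep_seed)
                coords = _as_coords(project_batch(trees, rvs))
                ids = split_ids
            else:
                dims = 2 if meth == "mds2" else 3
                emb = mds_embed(rf, dims=dims, seed=rep_seed,
                                max_iter=mds_max_iter)
                coords = emb.coordinates
                ids = mds_split_ids
            npts = len(coords)
            profiles = np.empty((npts, m_max + 1))
            for focal in range(npts):
                dvec = np.linalg.norm(coords - coords[focal], axis=1)
                dvec[focal] = -1.0  # focal always first; stable sort = index ties
                order = np.argsort(dvec, kind="stable")
                profiles[focal] = _resolution_profile(order, ids, m_max,
                                                      idx.dimension, n_internal)
            for m in range(m_max + 1):
                col = profiles[:, m]
                rows.append((meth, rep, m, float(col.min()),
                             float(col.mean()), float(col.max())))
    table = pd.DataFrame(rows, columns=["method", "replicate", "m",
                                        "min", "avg", "max"])
    config = dict(n=n, m_max=m_max, replicates=replicates,
                  methods=list(methods), seed=seed, k=k, d=d,
                  mds_max_iter=mds_max_iter, max_mds_trees=max_mds_trees)
    return LocalityTable(table=table, n=n, m_max=m_max, replicates=replicates,
                         methods=tuple(methods), seed=seed, config=config)


def dominance_check(table: LocalityTable, method: str, baseline: str,
                    alpha: float = 0.01,
                    m_range: range | None = None) -> dict[int, bool]:
    """Per-m check that ``method``'s mean average resolution is at least
    ``baseline``'s, allowing sampling error.

    Passes at a given m if the method's replicate mean is >= the
    baseline's, or if a one-sided Welch t-test cannot show the baseline
    greater at level ``alpha``.
    """
    if m_range is None:
        m_range = range(1, table.m_max + 1)
    df = table.table
    out = {}
    for m in m_range:
        a = df[(df["method"] == method) & (df["m"] == m)]["avg"].to_numpy()
        b = df[(df["method"] == baseline) & (df["m"] == m)]["avg"].to_numpy()
        if a.mean() >= b.mean():
            out[m] = True
            continue
        res = stats.ttest_ind(b, a, equal_var=False, alternative="greater")
        out[m] = bool(res.pvalue > alpha)
    return out
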