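"""Hierarchical cluster analysis of sub-data sets — the baseline selector.

Each pair of sub-data sets is compared by the Pearson correlation of their
intensities over the reduced Miller indices they have in common (each subset
pre-merged to one value per index).  Correlations become distances
(1 - CC by default), the distance matrix is clustered agglomeratively, and
the dendrogram is cut at a correlation cutoff; the largest resulting cluster
is the HCA selection for merging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .datasets import SubDataset

logger = logging.getLogger(__name__)

__all__ = ["DistanceMatrix", "pairwise_cc", "cluster_and_cut", "dendrogram_newick"]

MIN_COMMON_REFLECTIONS = 5
MAX_DISTANCE = 2.0


@dataclass
class DistanceMatrix:
    """Pairwise distances between sub-data sets plus pair support counts."""

    distances: np.ndarray  # (n, n), zero diagonal, symmetric, in [0, 2]
    n_common: np.ndarray  # (n, n) int, common unique reflections per pair
    subset_ids: tuple[str, ...]
    cc: np.ndarray | None = None  # raw correlations (NaN where unsupported)
    low_support_pairs: list[tuple[int, int]] = field(default_factory=list)
    isolated: list[int] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.subset_ids)


def pairwise_cc(pool: Sequence[SubDataset], distance: str = "one-minus-cc") -> DistanceMatrix:
    """Pairwise correlation distance matrix of a pool.

    Pairs sharing fewer than 5 unique reflections get the maximum distance
    (2) and are flagged; subsets overlapping with no other subset are listed
    as isolated.
    """
    if len(pool) < 2:
        raise ValueError("need at least two sub-data sets")
    for ds in pool:
        if not ds.reduced:
            raise ValueError(f"subset {ds.id!r} not reduced to the asymmetric unit")
    if distance not in ("one-minus-cc", "sqrt-one-minus-cc2"):
        raise ValueError(f"unknown distance transform {distance!r}")
    n = len(pool)
    # global key encoding across the pool
    mmax = max(int(np.abs(ds.hkl_red).max()) for ds in pool) + 1
    base = 2 * mmax + 1
    merged = []
    for ds in pool:
        h = ds.hkl_red.astype(np.int64)
        keys = (h[:, 0] * base + h[:, 1]) * base + h[:, 2]
        uniq, inv = np.unique(keys, return_inverse=True)
        means = np.bincount(inv, weights=ds.intensity) / np.bincount(inv)
        merged.append((uniq, means))

    dist = np.zeros((n, n))
    ncom = np.zeros((n, n), dtype=np.int64)
    cc = np.full((n, n), np.nan)
    np.fill_diagonal(cc, 1.0)
    low_support = []
    for i in range(n):
        ki, vi = merged[i]
        for j in range(i + 1, n):
            kj, vj = merged[j]
            common, ia, ja = np.intersect1d(ki, kj, assume_unique=True, return_indices=True)
            ncom[i, j] = ncom[j, i] = len(common)
            if len(common) < MIN_COMMON_REFLECTIONS:
                dist[i, j] = dist[j, i] = MAX_DISTANCE
                low_support.append((i, j))
                continue
            x, y = vi[ia], vj[ja]
            if np.std(x) == 0 or np.std(y) == 0:
                dist[i, j] = dist[j, i] = MAX_DISTANCE
                low_support.append((i, j))
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            cc[i, j] = cc[j, i] = r
            if distance == "one-minus-cc":
                dval = 1.0 - r
            else:
                dval = float(np.sqrt(max(0.0, 1.0 - r * r)))
            dist[i, j] = dist[j, i] = dval
    isolated = [i for i in range(n) if all(ncom[i, j] < MIN_COMMON_REFLECTIONS for j in range(n) if j != i)]
    for i in isolated:
        logger.warning("subset %r shares no reflections with any other subset", pool[i].id)
    return DistanceMatrix(
        distances=dist,
        n_common=ncom,
        subset_ids=tuple(ds.id for ds in pool),
        cc=cc,
        low_support_pairs=low_support,
        isolated=isolated,
    )


def _linkage(dm: DistanceMatrix, linkage: str) -> np.ndarray:
    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"unknown linkage {linkage!r}")
    return hierarchy.linkage(squareform(dm.distances, checks=False), method=linkage)


def cluster_and_cut(
    dm: DistanceMatrix, cc_cutoff: float, linkage: str = "average"
) -> list[list[int]]:
    """Cut the dendrogram at distance 1 - cc_cutoff; clusters sorted by size.

    Returns lists of pool indices, largest cluster first (the HCA selection).
    """
    if not -1.0 < cc_cutoff <= 1.0:
        raise ValueError("cc_cutoff must be in (-1, 1]")
    z = _linkage(dm, linkage)
    labels = hierarchy.fcluster(z, t=1.0 - cc_cutoff, criterion="distance")
    clusters: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        clusters.setdefault(int(lab), []).append(i)
    out = sorted(clusters.values(), key=lambda c: (-len(c), c[0]))
    if all(len(c) == 1 for c in out):
        logger.warning("cutoff %.3f yields only singleton clusters", cc_cutoff)
    return out


def dendrogram_newick(dm: DistanceMatrix, linkage: str = "average") -> str:
    """Newick serialization of the clustering dendrogram (branch lengths = merge heights)."""
    z = _linkage(dm, linkage)
    tree = hierarchy.to_tree(z)

    def walk(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{dm.subset_ids[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
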