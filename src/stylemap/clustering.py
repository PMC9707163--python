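"""Ward clustering of the dissimilarity matrix and k-means on its rows.

Ward's method merges, at each step, the pair of clusters with the smallest
increase in within-cluster variance; applied to an AUC dissimilarity
matrix the entries are treated as Euclidean distances (the standard
practice, with the caveat that AUCs need not embed exactly).  k-means is
run on the rows of the symmetric matrix as feature vectors — each group is
represented by its profile of dissimilarities to every group — with the
within-cluster sum of squared errors (WSS) curve over a k range as the
elbow diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .dissim import DissimilarityMatrix


@dataclass
class LinkageTree:
    """Agglomerative merge history in scipy linkage form.

    ``merges`` has one row per merge: (cluster_i, cluster_j, height,
    new_size), clusters numbered scipy-style (leaf i is cluster i, the
    m-th merge creates cluster n+m).
    """

    merges: np.ndarray  # (n-1, 4) scipy linkage matrix
    labels: list[str]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.merges.shape != (n - 1, 4):
            raise ValueError("linkage must have n-1 merge rows")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.merges, columns=["cluster_i", "cluster_j", "height", "new_size"]
        )


@dataclass
class KMeansResult:
    k: int
    assignments: dict[str, int]
    wss: float
    seed: int
    restarts: int


def _check_matrix(D: DissimilarityMatrix) -> np.ndarray:
    arr = np.asarray(D.values, dtype=float)
    if not np.allclose(arr, arr.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    return arr


def ward_linkage(D: DissimilarityMatrix) -> LinkageTree:
    """Ward agglomeration of the dissimilarity matrix.

    Entries are treated as pairwise Euclidean distances and merged under
    the Lance-Williams update for the Ward objective.  Merge heights are
    monotone non-decreasing (Ward admits no inversions).
    """
    arr = _check_matrix(D)
    if len(D.labels) < 2:
        raise ValueError("need at least 2 leaves")
    if not np.allclose(np.diag(arr), 0.0, atol=1e-10):
        raise ValueError("ward_linkage requires a zero diagonal")
    condensed = squareform(arr, checks=False)
    Z = hierarchy.linkage(condensed, method="ward")
    return LinkageTree(merges=Z, labels=list(D.labels))


def cut_tree(tree: LinkageTree, n_clusters: int) -> dict[str, int]:
    """Flat assignments from cutting the tree into ``n_clusters`` groups.

    Cluster ids are renumbered 0..n_clusters-1 in order of first
    appearance over the leaf order, so the output is deterministic.
    """
    n = len(tree.labels)
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters must be in [1, {n}], got {n_clusters}")
    raw = hierarchy.fcluster(tree.merges, t=n_clusters, criterion="maxclust")
    remap: dict[int, int] = {}
    out: dict[str, int] = {}
    for label, cid in zip(tree.labels, raw):
        if cid not in remap:
            remap[cid] = len(remap)
        out[label] = remap[cid]
    return out


def kmeans_rows(
    D: DissimilarityMatrix, k: int, restarts: int = 25, seed: int = 0
) -> KMeansResult:
    """k-means on the rows of the symmetric dissimilarity matrix.

    Each group's feature vector is its row of AUCs (including the
    diagonal entry under the active convention).  Lloyd iterations from
    k-means++ seeding, best of ``restarts`` runs by WSS.
    """
    arr = _check_matrix(D)
    n = len(D.labels)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels_arr = km.fit_predict(arr)
    return KMeansResult(
        k=k,
        assignments={lab: int(c) for lab, c in zip(D.labels, labels_arr)},
        wss=float(km.inertia_),
        seed=seed,
        restarts=restarts,
    )


def wss_curve(
    D: DissimilarityMatrix,
    k_min: int = 2,
    k_max: int = 9,
    restarts: int = 25,
    seed: int = 0,
) -> list[tuple[int, float]]:
    """Best WSS per k over ``[k_min, k_max]`` for the elbow diagnostic."""
    n = len(D.labels)
    if k_max > n:
        raise ValueError(f"k_max={k_max} exceeds the {n} groups")
    return [(k, kmeans_rows(D, k, restarts=restarts, seed=seed).wss) for k in range(k_min, k_max + 1)]
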