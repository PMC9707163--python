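"""Classical (Torgerson) multidimensional scaling and Procrustes alignment.

Classical MDS embeds a symmetric dissimilarity matrix by double-centering
the squared dissimilarities, ``B = -1/2 J D^2 J`` with ``J = I - 11'/n``,
and taking the top eigenvectors of ``B`` scaled by the square roots of
their eigenvalues.  The full eigenvalue spectrum is returned for scree
inspection; negative eigenvalues (the signature of a non-Euclidean input,
which classifier-AUC matrices generally are) are reported rather than
silently dropped, and are never used for coordinates.

Independently computed embeddings are only defined up to rotation,
reflection and translation, so the module also provides orthogonal
Procrustes alignment on a set of shared anchor points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import orthogonal_procrustes

from .dissim import DissimilarityMatrix

#: Eigenvalues within this relative tolerance of zero are treated as zero
#: when counting positive dimensions.
_EIG_TOL = 1e-9


@dataclass
class Embedding:
    """Coordinates and eigenvalue spectrum of a classical MDS solution."""

    labels: list[str]
    coords: np.ndarray  # (n, k)
    eigenvalues: np.ndarray  # full descending spectrum
    k: int

    def loc(self, label: str) -> np.ndarray:
        return self.coords[self.labels.index(label)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.coords,
            index=self.labels,
            columns=[f"dim{i + 1}" for i in range(self.k)],
        )


def _double_center(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ (D**2) @ J


def _as_array(D) -> tuple[np.ndarray, list[str]]:
    if isinstance(D, DissimilarityMatrix):
        return np.asarray(D.values, dtype=float), list(D.labels)
    D = np.asarray(D, dtype=float)
    return D, [str(i) for i in range(D.shape[0])]


def _validate(D: np.ndarray) -> None:
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise ValueError("classical MDS requires a zero diagonal")


def scree(D) -> np.ndarray:
    """Full descending eigenvalue spectrum of the double-centered matrix.

    Negative eigenvalues diagnose non-Euclidean input and are retained.
    """
    arr, _ = _as_array(D)
    _validate(arr)
    vals = np.linalg.eigvalsh(_double_center(arr))
    return vals[::-1]


def classical_mds(D, k: int = 2) -> Embedding:
    """Torgerson eigen-embedding of a symmetric zero-diagonal matrix.

    Coordinates are the top-``k`` eigenvectors of the double-centered
    squared-dissimilarity matrix scaled by the square roots of their
    (positive) eigenvalues; asking for more dimensions than there are
    positive eigenvalues is an error.  Each coordinate column's sign is
    fixed so its largest-magnitude entry is positive.
    """
    arr, labels = _as_array(D)
    _validate(arr)
    if k < 1:
        raise ValueError("k must be >= 1")
    B = _double_center(arr)
    vals, vecs = np.linalg.eigh(B)
    vals, vecs = vals[::-1], vecs[:, ::-1]
    tol = _EIG_TOL * max(1.0, float(np.abs(vals).max(initial=0.0)))
    n_pos = int(np.sum(vals > tol))
    if n_pos == 0 and np.allclose(arr, 0.0):
        # degenerate all-zero input: every point at the origin
        coords = np.zeros((arr.shape[0], k))
        return Embedding(labels=labels, coords=coords, eigenvalues=vals, k=k)
    if k > n_pos:
        raise ValueError(f"k={k} exceeds the {n_pos} positive eigenvalues available")
    coords = vecs[:, :k] * np.sqrt(vals[:k])
    for j in range(k):
        col = coords[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, j] = -col
    return Embedding(labels=labels, coords=coords, eigenvalues=vals, k=k)


def stress(D, emb: Embedding) -> float:
    """Normalized residual between input dissimilarities and embedding
    distances: ||D - D_hat||_F / ||D||_F (0 for Euclidean-realizable D)."""
    arr, _ = _as_array(D)
    diff = arr - distance_matrix(emb.coords)
    denom = np.linalg.norm(arr)
    return float(np.linalg.norm(diff) / denom) if denom else 0.0


def distance_matrix(coords: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import pdist, squareform

    return squareform(pdist(np.asarray(coords, dtype=float)))


def procrustes_align(
    reference: Embedding,
    target: Embedding,
    anchor_labels: Sequence[str] | None = None,
    translate: bool = True,
) -> tuple[Embedding, float]:
    """Rigidly align ``target`` onto ``reference`` using shared anchors.

    Finds the orthogonal transform (rotation/reflection, plus translation
    when ``translate``; never scaling) minimizing the squared error over
    the anchor points, applies it to *all* target points, and returns the
    aligned embedding together with the residual anchor sum of squares
    (the disparity).
    """
    if reference.k != target.k:
        raise ValueError("embeddings must share the same dimension k")
    k = reference.k
    anchors = list(anchor_labels) if anchor_labels is not None else list(reference.labels)
    missing = [a for a in anchors if a not in reference.labels or a not in target.labels]
    if missing:
        raise KeyError(f"anchors missing from an embedding: {missing}")
    if len(anchors) < k + 1:
        raise ValueError(f"need at least k+1={k + 1} anchors, got {len(anchors)}")

    R_anchor = np.vstack([reference.loc(a) for a in anchors])
    T_anchor = np.vstack([target.loc(a) for a in anchors])
    mu_r = R_anchor.mean(axis=0) if translate else np.zeros(k)
    mu_t = T_anchor.mean(axis=0) if translate else np.zeros(k)
    Q, _ = orthogonal_procrustes(T_anchor - mu_t, R_anchor - mu_r)
    aligned_coords = (target.coords - mu_t) @ Q + mu_r
    aligned = Embedding(
        labels=list(target.labels),
        coords=aligned_coords,
        eigenvalues=target.eigenvalues,
        k=k,
    )
    resid = np.vstack([aligned.loc(a) for a in anchors]) - R_anchor
    return aligned, float(np.sum(resid**2))
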