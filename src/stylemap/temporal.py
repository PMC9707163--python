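"""Anchored temporal trajectories of a focal group in style space.

To track how one group moves over time, its corpus is partitioned into
calendar slices (years, UTC, half-open intervals) and each slice is
embedded against a fixed set of *anchor* groups: anchor-anchor AUCs are
computed once and reused, per-slice focal-vs-anchor AUCs complete a full
dissimilarity matrix, classical MDS embeds it, and the embedding is
rigidly aligned (orthogonal Procrustes on the anchors) to the earliest
slice's embedding.  Holding the anchors constant attributes any movement
of the focal point to change in the focal group alone; the alignment
removes the rotation/reflection indeterminacy of independent MDS runs.

The per-axis trend over slices is summarized by a Spearman rank
correlation with an exact permutation p-value at small n.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .corpus_io import Comment
from .dissim import DissimConfig, DissimilarityMatrix, balanced_sample_size, pair_dissimilarity
from .geometry import Embedding, classical_mds, procrustes_align
from .seeds import derive_seed

logger = logging.getLogger(__name__)

#: Largest n for which the Spearman p-value is computed by exhaustive
#: permutation enumeration (n! grows past tractability above this).
EXACT_PERM_MAX_N = 9


@dataclass
class TrajectoryConfig:
    """Settings for anchored trajectory tracking.

    ``min_per_class`` is the smallest balanced per-class sample a slice
    must support against every anchor; smaller slices are skipped with a
    warning because their AUC estimates are too noisy.
    """

    seed: int = 0
    dissim: DissimConfig = field(default_factory=DissimConfig)
    min_per_class: int = 100
    k: int = 2
    focal_label: str = "focal"


@dataclass
class SliceTrajectory:
    """Aligned focal coordinates per time slice with per-axis trends."""

    slices: list
    coords: np.ndarray  # (n_slices, 2)
    trends: dict[str, tuple[float, float, int]]  # axis -> (rho, p, n)
    anchor_labels: list[str]
    anchor_coords: dict  # slice -> (n_anchors, 2) aligned anchor coords
    disparities: dict  # slice -> Procrustes anchor disparity
    excluded: list = field(default_factory=list)
    skipped: list = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.coords, index=self.slices, columns=["dim1", "dim2"]
        ).rename_axis("slice")

    def trend_json(self) -> str:
        return json.dumps(
            {
                "trends": {
                    ax: {"rho": r, "p": p, "n": n} for ax, (r, p, n) in self.trends.items()
                },
                "excluded": list(self.excluded),
                "skipped": list(self.skipped),
            },
            indent=2,
        )


def slice_by_period(comments: Iterable[Comment], period: str = "year") -> dict[int, list[Comment]]:
    """Partition comments by calendar period in UTC.

    Only yearly slicing is supported; intervals are half-open, so a
    timestamp at midnight on January 1 belongs to the new year.  Empty
    periods are omitted.
    """
    if period != "year":
        raise ValueError(f"unsupported period {period!r}")
    out: dict[int, list[Comment]] = {}
    for c in comments:
        year = datetime.fromtimestamp(c.created_utc, tz=timezone.utc).year
        out.setdefault(year, []).append(c)
    return dict(sorted(out.items()))


def spearman_trend(values: Sequence[float], times: Sequence[float]) -> tuple[float, float, int]:
    """Spearman rank correlation of ``values`` against ``times``.

    Ties receive average ranks.  The two-sided p-value is exact (full
    permutation enumeration of the value ranks) for n <= 9 and uses the
    t approximation on n-2 degrees of freedom otherwise.  Constant input
    leaves the correlation undefined and raises.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    if v.shape != t.shape or v.ndim != 1:
        raise ValueError("values and times must be equal-length 1-D sequences")
    n = len(v)
    if n < 3:
        raise ValueError(f"need at least 3 points for a trend, got {n}")
    if np.ptp(v) == 0 or np.ptp(t) == 0:
        raise ValueError("Spearman correlation undefined for constant input")

    rv = stats.rankdata(v)
    rt = stats.rankdata(t)
    rho = float(np.corrcoef(rv, rt)[0, 1])

    if n <= EXACT_PERM_MAX_N:
        perms = np.array(list(itertools.permutations(rv)))
        rt_c = rt - rt.mean()
        pv_c = perms - perms.mean(axis=1, keepdims=True)
        denom = np.sqrt((pv_c**2).sum(axis=1) * (rt_c**2).sum())
        rhos = (pv_c @ rt_c) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        tt = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(tt), df=n - 2))
    return rho, min(p, 1.0), n


def _anchor_matrix(
    anchors: Mapping[str, np.ndarray], config: TrajectoryConfig
) -> tuple[list[str], np.ndarray]:
    labels = list(anchors)
    n = len(labels)
    vals = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        a, b = sorted((labels[i], labels[j]))
        seed = derive_seed(config.seed, "pair", a, b)
        auc, _ = pair_dissimilarity(anchors[a], anchors[b], config.dissim, labels=(a, b), seed=seed)
        vals[i, j] = vals[j, i] = auc
    return labels, vals


def anchored_trajectory(
    focal_slices: Mapping, anchors: Mapping[str, np.ndarray], config: TrajectoryConfig | None = None
) -> SliceTrajectory:
    """Embed each focal time slice against fixed anchors and align.

    ``focal_slices`` maps slice labels (e.g. years) to featurized comment
    matrices; ``anchors`` maps anchor group labels to theirs.  The
    anchor-anchor AUC sub-matrix is computed once and reused for every
    slice, so it is bit-identical across slices.  Per slice, the full
    matrix is embedded with classical MDS and Procrustes-aligned to the
    earliest included slice using the anchor points; the focal group's
    aligned coordinates form the trajectory, and each axis gets a
    Spearman trend against the slice order.
    """
    config = config or TrajectoryConfig()
    if len(anchors) < 3:
        raise ValueError(f"need at least 3 anchors, got {len(anchors)}")
    if config.focal_label in anchors:
        raise ValueError(f"focal label {config.focal_label!r} collides with an anchor")

    anchor_labels, anchor_vals = _anchor_matrix(anchors, config)
    min_anchor_n = min(len(X) for X in anchors.values())

    included: list = []
    skipped: list = []
    coords_rows: list[np.ndarray] = []
    anchor_coords: dict = {}
    disparities: dict = {}
    reference: Embedding | None = None

    for slice_label in sorted(focal_slices):
        F = np.asarray(focal_slices[slice_label], dtype=float)
        if len(F) < 2 or balanced_sample_size(len(F), min_anchor_n) < config.min_per_class:
            logger.warning(
                "slice %s skipped: %d rows below the per-class minimum %d",
                slice_label, len(F), config.min_per_class,
            )
            skipped.append(slice_label)
            continue
        m = len(anchor_labels)
        vals = np.zeros((m + 1, m + 1))
        vals[:m, :m] = anchor_vals
        for i, a in enumerate(anchor_labels):
            seed = derive_seed(config.seed, "focal", str(slice_label), a)
            auc, _ = pair_dissimilarity(
                anchors[a], F, config.dissim, labels=(a, config.focal_label), seed=seed
            )
            vals[i, m] = vals[m, i] = auc
        D = DissimilarityMatrix(labels=anchor_labels + [config.focal_label], values=vals)
        emb = classical_mds(D, k=config.k)
        if reference is None:
            reference = emb
            aligned, disparity = emb, 0.0
        else:
            aligned, disparity = procrustes_align(reference, emb, anchor_labels)
        included.append(slice_label)
        coords_rows.append(aligned.loc(config.focal_label))
        anchor_coords[slice_label] = np.vstack([aligned.loc(a) for a in anchor_labels])
        disparities[slice_label] = disparity

    if not included:
        raise ValueError("no slice met the minimum size requirement")
    coords = np.vstack(coords_rows)
    trends = _trends(included, coords)
    return SliceTrajectory(
        slices=included,
        coords=coords,
        trends=trends,
        anchor_labels=anchor_labels,
        anchor_coords=anchor_coords,
        disparities=disparities,
        skipped=skipped,
    )


def _times(slices: Sequence) -> np.ndarray:
    try:
        return np.array([float(s) for s in slices])
    except (TypeError, ValueError):
        return np.arange(len(slices), dtype=float)


def _trends(slices: Sequence, coords: np.ndarray) -> dict[str, tuple[float, float, int]]:
    times = _times(slices)
    out: dict[str, tuple[float, float, int]] = {}
    for axis, name in enumerate(("dim1", "dim2")):
        try:
            out[name] = spearman_trend(coords[:, axis], times)
        except ValueError:
            out[name] = (float("nan"), float("nan"), len(slices))
    return out


def exclude_slice(trajectory: SliceTrajectory, slice_label) -> SliceTrajectory:
    """Drop one slice and recompute the per-axis trend statistics.

    The remaining aligned coordinates are unchanged (alignment to the
    original reference is kept); the exclusion is recorded.
    """
    if slice_label not in trajectory.slices:
        raise KeyError(f"slice {slice_label!r} not in trajectory")
    keep = [i for i, s in enumerate(trajectory.slices) if s != slice_label]
    slices = [trajectory.slices[i] for i in keep]
    coords = trajectory.coords[keep]
    return replace(
        trajectory,
        slices=slices,
        coords=coords,
        trends=_trends(slices, coords),
        anchor_coords={s: trajectory.anchor_coords[s] for s in slices},
        disparities={s: trajectory.disparities[s] for s in slices},
        excluded=list(trajectory.excluded) + [slice_label],
    )
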