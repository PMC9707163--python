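"""Optional matplotlib figures for the pipeline outputs.

matplotlib is imported lazily so the core pipeline has no hard plotting
dependency; install the ``plot`` extra to use this module.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .clustering import LinkageTree
from .geometry import Embedding
from .temporal import SliceTrajectory


def _plt():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def scatter_embedding(
    emb: Embedding, path, clusters: Mapping[str, int] | None = None
) -> None:
    """2-D map of the groups, optionally coloured by cluster id."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(7, 6))
    colors = [clusters.get(l, 0) for l in emb.labels] if clusters else None
    ax.scatter(emb.coords[:, 0], emb.coords[:, 1], c=colors, cmap="tab10")
    for label, (x, y) in zip(emb.labels, emb.coords[:, :2]):
        ax.annotate(label, (x, y), fontsize=8, xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("dimension 1")
    ax.set_ylabel("dimension 2")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def scree_plot(eigenvalues: Sequence[float], path) -> None:
    """Descending eigenvalue (elbow) plot; negatives shown below zero."""
    plt = _plt()
    vals = np.asarray(eigenvalues, dtype=float)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(np.arange(1, len(vals) + 1), vals, "o-")
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("component")
    ax.set_ylabel("eigenvalue")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def dendrogram_plot(tree: LinkageTree, path) -> None:
    """Ward merge dendrogram with leaf labels."""
    plt = _plt()
    from scipy.cluster import hierarchy

    fig, ax = plt.subplots(figsize=(8, 5))
    hierarchy.dendrogram(tree.merges, labels=tree.labels, ax=ax, leaf_rotation=90)
    ax.set_ylabel("merge height")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def trajectory_plot(traj: SliceTrajectory, path) -> None:
    """Focal path through style space with anchors from the first slice."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(7, 6))
    anchors = traj.anchor_coords[traj.slices[0]]
    ax.scatter(anchors[:, 0], anchors[:, 1], marker="s", color="grey", label="anchors")
    for label, (x, y) in zip(traj.anchor_labels, anchors):
        ax.annotate(label, (x, y), fontsize=7, color="grey",
                    xytext=(3, 3), textcoords="offset points")
    sc = ax.scatter(traj.coords[:, 0], traj.coords[:, 1],
                    c=np.arange(len(traj.slices)), cmap="coolwarm", zorder=3)
    ax.plot(traj.coords[:, 0], traj.coords[:, 1], "-", color="black", lw=0.8, zorder=2)
    cbar = fig.colorbar(sc, ax=ax, ticks=range(len(traj.slices)))
    cbar.ax.set_yticklabels([str(s) for s in traj.slices])
    ax.set_xlabel("dimension 1")
    ax.set_ylabel("dimension 2")
    ax.legend(loc="best")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
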