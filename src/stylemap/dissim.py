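"""Pairwise group dissimilarity as held-out classifier AUC.

For every unordered pair of groups, a balanced binary classification task
is built by random under-sampling (each class contributes the size of the
smaller group, rounded down to an even count), split 50:50 into train and
test halves, and a classifier — by default an extremely randomised tree
ensemble — is fit on the train half.  The AUC of its scores on the test
half is the dissimilarity: 0.5 means the two groups' style distributions
are indistinguishable, 1.0 means perfectly separable.  The C(n, 2) AUCs
are assembled into a symmetric labelled matrix suitable for embedding and
clustering.

All per-pair randomness (sampling, splitting, the ensemble) is derived
from one master seed and the sorted label pair, so the matrix is invariant
to the order in which groups are supplied.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.metrics import roc_auc_score

from .seeds import derive_seed

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairSamplingPlan:
    """Balanced under-sampling plan for one pairwise comparison.

    ``n_per_class`` comments are drawn from each group without
    replacement; ``n_total`` is the combined sample entering the 50:50
    train/test split.
    """

    group_a: str
    group_b: str
    n_per_class: int
    seed: int

    @property
    def n_total(self) -> int:
        return 2 * self.n_per_class

    def __post_init__(self) -> None:
        if self.n_per_class < 2 or self.n_per_class % 2:
            raise ValueError(
                f"n_per_class must be an even integer >= 2, got {self.n_per_class}"
            )


@dataclass
class DissimConfig:
    """Settings for pairwise AUC computation.

    The classifier defaults follow scikit-learn's extra-trees defaults
    (100 trees, sqrt(n_features) split candidates); the original analyses
    state none, and AUC estimates are insensitive to them at these sample
    sizes.  ``max_per_class`` optionally caps the under-sampled class size
    to bound runtime on very large corpora.
    """

    seed: int = 0
    n_estimators: int = 100
    max_features: str | int | float = "sqrt"
    train_frac: float = 0.5
    max_per_class: int | None = None
    min_per_class: int = 2
    diagonal: str = "zero"  # {"zero", "half"}

    def __post_init__(self) -> None:
        if self.train_frac != 0.5:
            raise ValueError("only the 50:50 train/test split is supported")
        if self.diagonal not in {"zero", "half"}:
            raise ValueError(f"unknown diagonal convention {self.diagonal!r}")


@dataclass
class DissimilarityMatrix:
    """Symmetric labelled matrix of pairwise AUC dissimilarities."""

    labels: list[str]
    values: np.ndarray
    diagonal_convention: str = "zero"
    plans: dict[tuple[str, str], PairSamplingPlan] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        off = v[~np.eye(len(self.labels), dtype=bool)]
        if off.size and (off.min() < 0 or off.max() > 1):
            raise ValueError("off-diagonal AUC entries must lie in [0, 1]")
        self.values = v

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    def reorder(self, labels: Sequence[str]) -> "DissimilarityMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DissimilarityMatrix(
            labels=list(labels),
            values=self.values[np.ix_(idx, idx)],
            diagonal_convention=self.diagonal_convention,
            plans=self.plans,
        )

    def plans_to_json(self) -> str:
        return json.dumps(
            {
                f"{a}|{b}": {"n_per_class": p.n_per_class, "n_total": p.n_total, "seed": p.seed}
                for (a, b), p in sorted(self.plans.items())
            },
            indent=2,
        )


def balanced_sample_size(n_a: int, n_b: int) -> int:
    """Per-class sample size under random under-sampling.

    The smaller group's size, rounded down to the nearest even integer so
    the 50:50 train/test split is integral in both halves.
    """
    m = min(int(n_a), int(n_b))
    if m < 2:
        raise ValueError(f"need at least 2 comments per group, got min={m}")
    return m - (m % 2)


def train_test_split_pair(
    A: np.ndarray, B: np.ndarray, plan: PairSamplingPlan
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Seeded balanced under-sample and 50:50 split.

    Draws ``plan.n_per_class`` rows uniformly without replacement from each
    group, assigns exactly half of each group's draw to the train half and
    half to the test half.  The positive class (label 1) is the
    lexicographically larger group label.

    Returns ``(X_train, y_train, X_test, y_test)``.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if plan.n_per_class > min(len(A), len(B)):
        raise ValueError(
            f"plan requires {plan.n_per_class} per class but groups have "
            f"{len(A)} and {len(B)} rows"
        )
    first_is_a = plan.group_a <= plan.group_b
    X0, X1 = (A, B) if first_is_a else (B, A)

    rng = np.random.default_rng(plan.seed)
    half = plan.n_per_class // 2
    parts_train, parts_test = [], []
    for X, y in ((X0, 0.0), (X1, 1.0)):
        idx = rng.choice(len(X), size=plan.n_per_class, replace=False)
        parts_train.append((X[idx[:half]], np.full(half, y)))
        parts_test.append((X[idx[half:]], np.full(half, y)))
    X_train = np.vstack([p[0] for p in parts_train])
    y_train = np.concatenate([p[1] for p in parts_train])
    X_test = np.vstack([p[0] for p in parts_test])
    y_test = np.concatenate([p[1] for p in parts_test])
    return X_train, y_train, X_test, y_test


def auc_from_scores(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC of real-valued scores against binary labels.

    Mann-Whitney formulation: the fraction of (positive, negative) pairs
    where the positive scores higher, ties counting one half.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute an AUC")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def auc_to_distance(auc: float | np.ndarray) -> float | np.ndarray:
    """Optional affine transform mapping the 0.5 chance baseline to 0:
    ``d = max(0, 2*AUC - 1)``."""
    return np.maximum(0.0, 2.0 * np.asarray(auc, dtype=float) - 1.0)


def _make_classifier(config: DissimConfig, seed: int) -> ExtraTreesClassifier:
    return ExtraTreesClassifier(
        n_estimators=config.n_estimators,
        max_features=config.max_features,
        random_state=seed,
        n_jobs=1,
    )


def pair_dissimilarity(
    A: np.ndarray,
    B: np.ndarray,
    config: DissimConfig,
    labels: tuple[str, str] = ("a", "b"),
    seed: int | None = None,
) -> tuple[float, PairSamplingPlan]:
    """Held-out AUC of a balanced classifier separating two feature matrices.

    All configured features are used.  Degenerate (all-constant) inputs
    trigger a warning but the AUC is still computed (it will sit near 0.5).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if seed is None:
        seed = config.seed
    n_pc = balanced_sample_size(len(A), len(B))
    if config.max_per_class is not None:
        n_pc = min(n_pc, config.max_per_class - (config.max_per_class % 2))
    if n_pc < config.min_per_class:
        raise ValueError(
            f"pair {labels}: balanced per-class size {n_pc} below minimum "
            f"{config.min_per_class}"
        )
    plan = PairSamplingPlan(group_a=labels[0], group_b=labels[1], n_per_class=n_pc, seed=seed)
    X_train, y_train, X_test, y_test = train_test_split_pair(A, B, plan)
    if np.all(np.ptp(np.vstack([X_train, X_test]), axis=0) == 0):
        warnings.warn(f"pair {labels}: all features constant; AUC is uninformative")
    clf = _make_classifier(config, derive_seed(seed, "clf"))
    clf.fit(X_train, y_train)
    scores = clf.predict_proba(X_test)[:, 1]
    return auc_from_scores(scores, y_test.astype(int)), plan


def build_matrix(
    groups: Mapping[str, np.ndarray], config: DissimConfig | None = None
) -> DissimilarityMatrix:
    """AUC dissimilarity matrix over all unordered group pairs.

    One classifier per pair (C(n, 2) models).  Per-pair seeds are derived
    from the master seed and the sorted label pair, making the result
    invariant to input order up to row/column permutation.
    """
    config = config or DissimConfig()
    labels = list(groups)
    if len(labels) < 3:
        raise ValueError(f"need at least 3 groups, got {len(labels)}")
    for lab, X in groups.items():
        if len(X) < config.min_per_class:
            raise ValueError(
                f"group {lab!r} has {len(X)} rows, below the per-class minimum "
                f"{config.min_per_class}"
            )
    n = len(labels)
    diag = 0.0 if config.diagonal == "zero" else 0.5
    values = np.full((n, n), diag)
    plans: dict[tuple[str, str], PairSamplingPlan] = {}
    for i, j in itertools.combinations(range(n), 2):
        a, b = sorted((labels[i], labels[j]))
        seed = derive_seed(config.seed, "pair", a, b)
        auc, plan = pair_dissimilarity(groups[a], groups[b], config, labels=(a, b), seed=seed)
        values[i, j] = values[j, i] = auc
        plans[(a, b)] = plan
        logger.info("pair %s|%s n_per_class=%d auc=%.4f seed=%d", a, b, plan.n_per_class, auc, seed)
    return DissimilarityMatrix(
        labels=labels, values=values, diagonal_convention=config.diagonal, plans=plans
    )
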