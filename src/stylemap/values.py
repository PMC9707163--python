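"""Value-lexicon scoring of group corpora and regression onto MDS axes.

Each post is scored against a ten-category personal-values lexicon
(achievement, benevolence, conformity, hedonism, power, security,
self-direction, stimulation, tradition, universalism): the score for a
value is the percentage of the post's tokens matching that value's
patterns.  Group-level value scores are unweighted means over posts.

To relate value content to position in style space, each of the ten value
scores is regressed (OLS with intercept) on the two MDS coordinates
across groups, giving unstandardized slopes, standard errors, t-based 95%
confidence intervals, R-squared and an overall F-test p-value per value —
one table row per value.  Raw p-values are reported without
multiple-testing correction across the ten regressions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .corpus_io import Comment
from .lexicon import CategoryLexicon, score_document

#: Canonical order of the ten basic personal values.
VALUE_CATEGORIES = (
    "achievement",
    "benevolence",
    "conformity",
    "hedonism",
    "power",
    "security",
    "self-direction",
    "stimulation",
    "tradition",
    "universalism",
)


@dataclass
class ValueScores:
    """Per-group mean percentages over the ten value categories."""

    group: str
    means: np.ndarray  # aligned with VALUE_CATEGORIES

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        if self.means.shape != (len(VALUE_CATEGORIES),):
            raise ValueError("means must have one entry per value category")
        if self.means.min() < 0 or self.means.max() > 100:
            raise ValueError("value means must lie in [0, 100]")


@dataclass
class ValueRegression:
    """One row of the value-on-coordinates regression table."""

    value: str
    b1: float
    se1: float
    ci1: tuple[float, float]
    b2: float
    se2: float
    ci2: tuple[float, float]
    r_squared: float
    p_value: float


def _check_value_lexicon(lexicon: CategoryLexicon) -> None:
    declared = set(lexicon.categories)
    expected = set(VALUE_CATEGORIES)
    if declared != expected:
        raise ValueError(
            "value lexicon must declare exactly the ten value categories; "
            f"missing={sorted(expected - declared)} extra={sorted(declared - expected)}"
        )


def score_values(
    comments_by_group: Mapping[str, Sequence[Comment]], value_lexicon: CategoryLexicon
) -> list[ValueScores]:
    """Mean per-post value percentages for each group.

    The mean is unweighted by post length: every post contributes its own
    percentage vector equally.
    """
    _check_value_lexicon(value_lexicon)
    out: list[ValueScores] = []
    for group, comments in comments_by_group.items():
        if not comments:
            raise ValueError(f"group {group!r} has zero posts")
        rows = np.vstack(
            [score_document(c.body, value_lexicon, VALUE_CATEGORIES).values for c in comments]
        )
        out.append(ValueScores(group=group, means=rows.mean(axis=0)))
    return out


def value_scores_frame(scores: Sequence[ValueScores]) -> pd.DataFrame:
    return pd.DataFrame(
        [s.means for s in scores],
        index=[s.group for s in scores],
        columns=list(VALUE_CATEGORIES),
    )


def regress_value_on_coords(
    value_means: Sequence[float], coords: np.ndarray, value_name: str = "value"
) -> ValueRegression:
    """OLS of one value's group means on the two MDS coordinates.

    Intercept included; slopes are unstandardized; confidence intervals
    are two-sided t-based 95% intervals on n-3 residual degrees of
    freedom; the p-value is from the overall F test.
    """
    y = np.asarray(value_means, dtype=float)
    X = np.asarray(coords, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("coords must be an (n, 2) matrix")
    if len(y) != len(X):
        raise ValueError("value means and coordinates must have equal length")
    if len(y) < 4:
        raise ValueError("need at least 4 groups (intercept + 2 slopes + 1 residual df)")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design: coordinates are collinear")
    if np.ptp(y) == 0:
        # constant outcome: slopes are zero, nothing to explain, no
        # evidence against the null (statsmodels leaves R^2/F undefined)
        fit = sm.OLS(y, design).fit()
        ci = fit.conf_int(alpha=0.05)
        p, r2 = 1.0, 0.0
    else:
        fit = sm.OLS(y, design).fit()
        ci = fit.conf_int(alpha=0.05)
        p, r2 = float(fit.f_pvalue), float(fit.rsquared)
        if not np.isfinite(p):
            p = 1.0
    return ValueRegression(
        value=value_name,
        b1=float(fit.params[1]),
        se1=float(fit.bse[1]),
        ci1=(float(ci[1, 0]), float(ci[1, 1])),
        b2=float(fit.params[2]),
        se2=float(fit.bse[2]),
        ci2=(float(ci[2, 0]), float(ci[2, 1])),
        r_squared=r2,
        p_value=p,
    )


def run_value_table(
    value_scores: Sequence[ValueScores], coords_by_group: Mapping[str, np.ndarray]
) -> pd.DataFrame:
    """Ten independent regressions, one row per value.

    Columns mirror the standard reporting layout: unstandardized B, SE and
    95% CI per dimension, plus R-squared and the model p-value.
    """
    groups = [s.group for s in value_scores]
    missing = [g for g in groups if g not in coords_by_group]
    if missing:
        raise KeyError(f"groups missing coordinates: {missing}")
    coords = np.vstack([coords_by_group[g] for g in groups])
    frame = value_scores_frame(value_scores)
    rows = []
    for value in VALUE_CATEGORIES:
        r = regress_value_on_coords(frame[value].to_numpy(), coords, value_name=value)
        rows.append(
            {
                "value": r.value,
                "b_dim1": r.b1,
                "se_dim1": r.se1,
                "ci_low_dim1": r.ci1[0],
                "ci_high_dim1": r.ci1[1],
                "b_dim2": r.b2,
                "se_dim2": r.se2,
                "ci_low_dim2": r.ci2[0],
                "ci_high_dim2": r.ci2[1],
                "r_squared": r.r_squared,
                "p_value": r.p_value,
            }
        )
    return pd.DataFrame(rows).set_index("value")
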