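"""Value scoring of group corpora and regressions on embedding axes."""

import numpy as np
import pandas as pd
import pytest

from stylemap.lexicon import load_default_value_lexicon, parse_dictionary
from stylemap.values import (
    VALUE_CATEGORIES,
    ValueScores,
    regress_value_on_coords,
    run_value_table,
    score_values,
    value_scores_frame,
)

from conftest import make_comment


def ols_normal_equations(y, coords):
    """Textbook closed-form OLS oracle: beta = (X'X)^-1 X'y, with the
    standard error, CI and R^2 formulas computed from first principles."""
    from scipy import stats

    n = len(y)
    X = np.column_stack([np.ones(n), coords])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    df = n - X.shape[1]
    s2 = resid @ resid / df
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    tcrit = stats.t.ppf(0.975, df)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - (resid @ resid) / ss_tot
    return beta, se, tcrit, r2


@pytest.fixture(scope="module")
def value_lexicon():
    return load_default_value_lexicon()


class TestScoreValues:
    def test_unweighted_mean_of_post_percentages(self, value_lexicon):
        # post 1: 1 of 100 tokens is a benevolence word -> 1.0
        # post 2: 3 of 100 -> 3.0; the group mean is 2.0 regardless of length
        filler = " ".join(f"x{i}" for i in range(99))
        filler2 = " ".join(f"y{i}" for i in range(97))
        posts = {
            "g": [
                make_comment(filler + " kindness"),
                make_comment(filler2 + " helpful helping kind"),
            ]
        }
        (scores,) = score_values(posts, value_lexicon)
        idx = VALUE_CATEGORIES.index("benevolence")
        assert scores.means[idx] == pytest.approx(2.0)

    def test_no_matches_all_zero(self, value_lexicon):
        posts = {"g": [make_comment("zz qq ww")]}
        (scores,) = score_values(posts, value_lexicon)
        assert np.all(scores.means == 0)

    def test_elevated_category_has_highest_mean(self, value_lexicon):
        from stylemap.synthgen import make_group_corpus, StyleProfile

        # emit achievement-lexicon stems far above everything else
        profile = StyleProfile(category_probs={"achiev": 0.2}, doc_length=(80, 5))
        corpus = make_group_corpus(profile, 50, seed=0)
        # tokens are "achievw<i>", which the stem achiev* matches
        (scores,) = score_values({"g": corpus}, value_lexicon)
        assert int(np.argmax(scores.means)) == VALUE_CATEGORIES.index("achievement")

    def test_zero_post_group_named(self, value_lexicon):
        with pytest.raises(ValueError, match="empty_group"):
            score_values({"empty_group": []}, value_lexicon)

    def test_wrong_category_set_rejected(self):
        lex = parse_dictionary("%\n1 achievement\n%\nwin 1\n")
        with pytest.raises(ValueError, match="ten value categories"):
            score_values({"g": [make_comment("win")]}, lex)

    def test_means_within_post_score_range(self, value_lexicon):
        posts = {
            "g": [
                make_comment("help kind " + " ".join(f"x{i}" for i in range(8))),
                make_comment(" ".join(f"y{i}" for i in range(10))),
            ]
        }
        (scores,) = score_values(posts, value_lexicon)
        idx = VALUE_CATEGORIES.index("benevolence")
        assert 0.0 <= scores.means[idx] <= 20.0


class TestRegressValueOnCoords:
    def test_exact_linear_relation(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(10, 2))
        y = 1.0 + 2.5 * coords[:, 0] - 1.5 * coords[:, 1]
        r = regress_value_on_coords(y, coords)
        assert r.b1 == pytest.approx(2.5, abs=1e-10)
        assert r.b2 == pytest.approx(-1.5, abs=1e-10)
        assert r.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_constant_outcome(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(8, 2))
        r = regress_value_on_coords(np.full(8, 3.0), coords)
        assert r.b1 == pytest.approx(0.0, abs=1e-10)
        assert r.b2 == pytest.approx(0.0, abs=1e-10)
        assert r.r_squared == pytest.approx(0.0, abs=1e-10)
        assert r.p_value == 1.0

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(15, 2))
        y = 0.5 + 0.8 * coords[:, 0] - 0.3 * coords[:, 1] + 0.2 * rng.normal(size=15)
        r = regress_value_on_coords(y, coords)
        beta, se, tcrit, r2 = ols_normal_equations(y, coords)
        assert r.b1 == pytest.approx(beta[1], abs=1e-8)
        assert r.b2 == pytest.approx(beta[2], abs=1e-8)
        assert r.se1 == pytest.approx(se[1], abs=1e-8)
        assert r.se2 == pytest.approx(se[2], abs=1e-8)
        assert r.ci1[0] == pytest.approx(beta[1] - tcrit * se[1], abs=1e-8)
        assert r.ci1[1] == pytest.approx(beta[1] + tcrit * se[1], abs=1e-8)
        assert r.r_squared == pytest.approx(r2, abs=1e-8)

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(12, 2))
        y = coords[:, 0] + rng.normal(size=12)
        r = regress_value_on_coords(y, coords)
        assert r.ci1[0] <= r.b1 <= r.ci1[1]
        assert r.ci2[0] <= r.b2 <= r.ci2[1]

    def test_r2_invariant_under_axis_rescaling(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(15, 2))
        y = 0.7 * coords[:, 0] - 0.2 * coords[:, 1] + 0.1 * rng.normal(size=15)
        r = regress_value_on_coords(y, coords)
        scaled = coords * np.array([10.0, 0.5])
        rs = regress_value_on_coords(y, scaled)
        assert rs.r_squared == pytest.approx(r.r_squared, abs=1e-10)
        assert rs.b1 == pytest.approx(r.b1 / 10.0, abs=1e-10)
        assert rs.b2 == pytest.approx(r.b2 / 0.5, abs=1e-10)

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            regress_value_on_coords([1.0, 2.0, 3.0], np.eye(3, 2))

    def test_collinear_design_rejected(self):
        coords = np.column_stack([np.arange(6.0), 2 * np.arange(6.0)])
        with pytest.raises(ValueError, match="rank"):
            regress_value_on_coords(np.arange(6.0), coords)


class TestRunValueTable:
    def _scores_and_coords(self, seed=0, n=15, planted_axis=None):
        rng = np.random.default_rng(seed)
        coords = {f"g{i}": rng.normal(size=2) for i in range(n)}
        X = np.vstack(list(coords.values()))
        scores = []
        for vi, value in enumerate(VALUE_CATEGORIES):
            if planted_axis is not None and value == "power":
                y = 3.0 + 2.0 * X[:, planted_axis] + 0.05 * rng.normal(size=n)
            else:
                y = 3.0 + 0.5 * rng.normal(size=n)
            scores.append(np.clip(y, 0, 100))
        per_group = np.vstack(scores).T
        vs = [ValueScores(group=f"g{i}", means=per_group[i]) for i in range(n)]
        return vs, coords

    def test_ten_rows_out(self):
        vs, coords = self._scores_and_coords()
        table = run_value_table(vs, coords)
        assert list(table.index) == list(VALUE_CATEGORIES)
        assert {"b_dim1", "se_dim2", "r_squared", "p_value"} <= set(table.columns)

    def test_group_order_invariance(self):
        vs, coords = self._scores_and_coords(seed=5)
        t1 = run_value_table(vs, coords)
        t2 = run_value_table(list(reversed(vs)), coords)
        pd.testing.assert_frame_equal(t1, t2)

    def test_planted_effect_detected_on_right_axis(self):
        vs, coords = self._scores_and_coords(seed=6, planted_axis=0)
        table = run_value_table(vs, coords)
        row = table.loc["power"]
        assert abs(row.b_dim1) > 1.0
        assert row.ci_low_dim2 < 0 < row.ci_high_dim2  # dim-2 CI covers zero
        assert row.p_value < 0.01

    def test_missing_coordinates_error(self):
        vs, coords = self._scores_and_coords()
        coords.pop("g3")
        with pytest.raises(KeyError, match="g3"):
            run_value_table(vs, coords)


def test_value_scores_frame_layout():
    vs = [ValueScores(group="a", means=np.arange(10.0)),
          ValueScores(group="b", means=np.arange(10.0) / 2)]
    frame = value_scores_frame(vs)
    assert frame.shape == (2, 10)
    assert list(frame.columns) == list(VALUE_CATEGORIES)
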