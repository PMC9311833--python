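"""SUDEP-7 scoring, binned-F feature screening and Spearman correlation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from perfuse_sudep.sudep import (
    DEFAULT_WEIGHTS,
    SudepError,
    score_sudep7,
    screen_features,
    spearman,
)


def test_score_zero_and_ceiling():
    zero = score_sudep7([0] * 7)
    assert zero.score == 0 and zero.stratum == "low"
    # maximum under the exclusion rules: i1, i4, i5, i6, i7
    top = score_sudep7([1, 1, 1, 1, 1, 1, 1])
    assert top.score == 10


def test_exclusion_rules_zero_dependent_items():
    # i2 alone scores, but contributes nothing once i1 is present
    assert score_sudep7([0, 1, 0, 0, 0, 0, 0]).score == 1
    assert score_sudep7([1, 1, 0, 0, 0, 0, 0]).score == 2
    # i3 alone scores, but contributes nothing once i4 is present
    assert score_sudep7([0, 0, 1, 0, 0, 0, 0]).score == 1
    assert score_sudep7([0, 0, 1, 1, 0, 0, 0]).score == 2


def test_high_risk_stratification_boundary():
    # weights (2,1,1,2,2,2,2): i1+i2+i3 -> 5 (low); i1+i3+i6 -> 6... build exact
    five = score_sudep7([1, 0, 1, 0, 1, 0, 0])  # 2+1+2
    assert five.score == 5 and five.stratum == "low"
    six = score_sudep7([1, 0, 0, 0, 1, 1, 0])  # 2+2+2
    assert six.score == 6 and six.stratum == "high"


def test_score_is_monotone_in_items():
    """Setting any single item true never decreases the score (all 128 cases)."""
    for items in itertools.product([0, 1], repeat=7):
        base = score_sudep7(items).score
        for j in range(7):
            if not items[j]:
                bumped = list(items)
                bumped[j] = 1
                assert score_sudep7(bumped).score >= base


def test_weights_exceeding_ceiling_rejected():
    with pytest.raises(SudepError, match="ceiling"):
        score_sudep7([1] * 7, weights=(3, 1, 1, 3, 3, 3, 3))


def _frame(columns):
    X = pd.DataFrame(columns)
    X.index = [f"P{i}" for i in range(len(X))]
    return X


def test_screen_constant_outcome_gives_zero_f():
    rng = np.random.default_rng(0)
    X = _frame({"a": rng.normal(size=9), "b": rng.normal(size=9)})
    y = pd.Series(5.0, index=X.index)
    out = screen_features(X, y)
    assert (out.loc[~out.flag, "F"] == 0).all()
    assert (out.loc[~out.flag, "p"] == 1.0).all()


def test_screen_flags_constant_predictor():
    rng = np.random.default_rng(1)
    X = _frame({"flat": np.ones(9), "ok": rng.normal(size=9)})
    y = pd.Series([3, 5, 7, 7, 7, 4, 7, 7, 4], index=X.index, dtype=float)
    out = screen_features(X, y)
    assert bool(out.loc["flat", "flag"])
    assert out.loc["flat", "rank"] == len(out)  # degenerate ranks last


def test_screen_matches_oneway_anova_oracle():
    """Two clean predictor modes: the binned F equals scipy's one-way ANOVA
    on the same grouping, and beats a shuffled-outcome variant."""
    x = np.r_[np.zeros(5), np.full(4, 0.3)]
    y = pd.Series(np.r_[np.full(5, 7.0), [3, 5, 4, 4]], index=[f"P{i}" for i in range(9)])
    X = _frame({"signal": x})
    out = screen_features(X, y)
    f_ref, p_ref = stats.f_oneway(y[:5], y[5:])
    assert out.loc["signal", "F"] == pytest.approx(f_ref)
    assert out.loc["signal", "p"] == pytest.approx(p_ref)
    rng = np.random.default_rng(2)
    worse = 0
    for _ in range(20):
        ys = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        shuffled = screen_features(X, ys)
        worse += shuffled.loc["signal", "F"] <= out.loc["signal", "F"]
    assert worse >= 18  # the aligned outcome is essentially never beaten


def test_screen_is_affine_invariant_in_the_predictor():
    rng = np.random.default_rng(3)
    X = _frame({"a": rng.normal(size=9), "b": rng.normal(size=9)})
    y = pd.Series([3, 5, 7, 7, 7, 4, 7, 7, 4], index=X.index, dtype=float)
    base = screen_features(X, y)
    scaled = screen_features(X * 13.7 - 4.2, y)
    pd.testing.assert_frame_equal(base, scaled)


def test_spearman_examples_and_errors():
    assert spearman([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)
    assert spearman([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)
    # tied data -> mid-rank Pearson by hand: rho = 0.5
    assert spearman([1, 1, 2], [1, 2, 2]) == pytest.approx(0.5)
    with pytest.raises(SudepError, match="constant"):
        spearman([1, 1, 1], [1, 2, 3])
    with pytest.raises(SudepError, match="length"):
        spearman([1, 2], [1, 2])
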