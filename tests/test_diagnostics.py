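import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from rai_toolkit import (
    TwoByTwo,
    chi_square,
    contingency,
    mann_whitney,
    metrics_from_2x2,
    roc_auc,
)
from rai_toolkit.diagnostics import (
    DiagnosticsError,
    format_p,
    format_pct,
)

# 2x2 of renal-angina status against severe day-3 AKI assembled from the
# published group counts: 89 RA+ of whom 54 severe, 357 RA- of whom 15.
SEVERE_TABLE = TwoByTwo(tp=54, fp=35, fn=15, tn=342)


def _vectors_for(table):
    pred = [True] * (table.tp + table.fp) + [False] * (table.fn + table.tn)
    out = (
        [True] * table.tp
        + [False] * table.fp
        + [True] * table.fn
        + [False] * table.tn
    )
    return pred, out


def test_contingency_reproduces_group_counts():
    pred, out = _vectors_for(SEVERE_TABLE)
    assert contingency(pred, out) == SEVERE_TABLE


def test_contingency_degenerate_cases():
    assert contingency([False] * 5, [False] * 5) == TwoByTwo(0, 0, 0, 5)
    assert contingency([True, False, True], [True, False, True]) == TwoByTwo(2, 0, 0, 1)
    with pytest.raises(DiagnosticsError):
        contingency([True], [True, False])


def test_metrics_on_severe_aki_table():
    m = metrics_from_2x2(SEVERE_TABLE)
    assert m.sensitivity == pytest.approx(54 / 69, abs=1e-4)
    assert m.specificity == pytest.approx(342 / 377, abs=1e-4)
    assert m.ppv == pytest.approx(54 / 89, abs=1e-4)
    assert m.npv == pytest.approx(342 / 357, abs=1e-4)
    # PPV is exactly the severe-AKI rate among RA+ patients
    assert format_pct(100 * m.ppv) == "60.7"


def test_metrics_degenerate_denominators():
    perfect = metrics_from_2x2(TwoByTwo(10, 0, 0, 10))
    assert (perfect.sensitivity, perfect.specificity, perfect.ppv, perfect.npv) == (
        1.0,
        1.0,
        1.0,
        1.0,
    )
    degenerate = metrics_from_2x2(TwoByTwo(0, 0, 5, 5))
    assert degenerate.sensitivity == 0.0
    assert math.isnan(degenerate.ppv)


@given(
    tp=st.integers(0, 50),
    fp=st.integers(0, 50),
    fn=st.integers(0, 50),
    tn=st.integers(0, 50),
)
def test_metrics_reproduce_integer_counts(tp, fp, fn, tn):
    m = metrics_from_2x2(TwoByTwo(tp, fp, fn, tn))
    if tp + fn:
        assert round(m.sensitivity * (tp + fn)) == tp
    if tn + fp:
        assert round(m.specificity * (tn + fp)) == tn


# ---------------------------------------------------------------------------
# ROC / AUC


def oracle_auc(scores, outcomes):
    """Mean over all positive-negative pairs of win + half-tie credit."""
    pos = [s for s, o in zip(scores, outcomes) if o]
    neg = [s for s, o in zip(scores, outcomes) if not o]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_auc_perfect_and_constant():
    _, auc = roc_auc([1, 2, 3, 10, 11, 12], [False] * 3 + [True] * 3)
    assert auc == pytest.approx(1.0)
    _, auc_tied = roc_auc([5.0] * 6, [False] * 3 + [True] * 3)
    assert auc_tied == pytest.approx(0.5)


def test_auc_single_class_errors():
    with pytest.raises(DiagnosticsError):
        roc_auc([1.0, 2.0], [True, True])


def test_auc_matches_pairwise_oracle_on_small_instances():
    rng = np.random.default_rng(11)
    for _ in range(200):
        n = int(rng.integers(2, 13))
        scores = rng.choice([0.0, 0.5, 1.0, 2.0, 3.5], size=n).tolist()
        outcomes = rng.random(n) < 0.5
        if outcomes.all() or not outcomes.any():
            continue
        _, auc = roc_auc(scores, outcomes)
        assert auc == pytest.approx(oracle_auc(scores, outcomes), abs=1e-12)


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(5)
    scores = rng.normal(size=30)
    outcomes = rng.random(30) < 0.4
    _, auc = roc_auc(scores, outcomes)
    _, auc_exp = roc_auc(np.exp(scores), outcomes)
    _, auc_rank = roc_auc(np.argsort(np.argsort(scores)).astype(float), outcomes)
    assert auc_exp == pytest.approx(auc)
    assert auc_rank == pytest.approx(auc)


# ---------------------------------------------------------------------------
# chi-square


def oracle_chi2_statistic(table):
    """Textbook Pearson formula."""
    arr = np.asarray(table, float)
    row = arr.sum(axis=1, keepdims=True)
    col = arr.sum(axis=0, keepdims=True)
    expected = row @ col / arr.sum()
    return float(((arr - expected) ** 2 / expected).sum())


def test_chi_square_independence():
    stat, p = chi_square([[10, 10], [10, 10]])
    assert stat == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_chi_square_severe_table_highly_significant():
    _, p = chi_square(SEVERE_TABLE)
    assert p < 0.001


def test_chi_square_matches_textbook_oracle():
    rng = np.random.default_rng(23)
    for _ in range(50):
        arr = rng.integers(1, 40, size=(2, 2))
        stat, _ = chi_square(arr.tolist())
        assert stat == pytest.approx(oracle_chi2_statistic(arr), abs=1e-9)
    doubled = [[20, 10], [10, 10]]
    stat, _ = chi_square(doubled)
    assert stat == pytest.approx(oracle_chi2_statistic(doubled), abs=1e-9)


def test_chi_square_zero_marginal_errors():
    with pytest.raises(DiagnosticsError):
        chi_square([[0, 0], [5, 5]])


# ---------------------------------------------------------------------------
# Mann-Whitney


def oracle_u(a, b):
    return sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in a for y in b)


def test_mann_whitney_identical_samples():
    sample = [float(i) for i in range(10)]
    _, p = mann_whitney(sample, sample)
    assert p > 0.9


def test_mann_whitney_complete_separation():
    u, _ = mann_whitney([1, 2, 3], [4, 5, 6])
    assert u == 0.0


def test_mann_whitney_matches_pairwise_oracle():
    rng = np.random.default_rng(31)
    for _ in range(300):
        a = rng.choice([0, 1, 2, 3, 4.5], size=int(rng.integers(1, 11))).tolist()
        b = rng.choice([0, 1, 2, 3, 4.5], size=int(rng.integers(1, 11))).tolist()
        u, p = mann_whitney(a, b)
        assert u == pytest.approx(oracle_u(a, b))
        assert 0.0 < p <= 1.0


# ---------------------------------------------------------------------------
# formatting


@pytest.mark.parametrize(
    "value,expected",
    [(60.674157, "60.7"), (31.460674, "31.5"), (2.25, "2.3"), (4.2016806, "4.2")],
)
def test_percent_formatting_rounds_half_up(value, expected):
    assert format_pct(value) == expected


def test_p_value_formatting():
    assert format_p(0.0004) == "<.001"
    assert format_p(0.0213) == "0.0213"
    assert format_p(None) == "NA"
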