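"""Fractional ranks, concentration/Erreygers indices, curves, and their SEs."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ineqdecomp.inequality import (
    RankedOutcome,
    concentration_curve,
    concentration_index,
    convenient_regression_slope,
    erreygers_index,
    fractional_rank,
    index_standard_error,
)
from ineqdecomp.survey_data import DegenerateBoundsError, UndefinedIndexError


# ---------------------------------------------------------------------------
# Fractional ranks
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "wealth, weights, expected",
    [
        ([10, 20, 30, 40], None, [0.125, 0.375, 0.625, 0.875]),
        ([1.0, 2.0], [1.0, 3.0], [0.125, 0.625]),
        ([5, 5, 5], [1.0, 2.0, 7.0], [0.5, 0.5, 0.5]),
    ],
)
def test_fractional_rank_hand_examples(wealth, weights, expected):
    np.testing.assert_allclose(fractional_rank(wealth, weights), expected, atol=1e-15)


def test_fractional_rank_unsorted_input_is_aligned():
    r = fractional_rank([30, 10, 40, 20])
    np.testing.assert_allclose(r, [0.625, 0.125, 0.875, 0.375])


@settings(derandomize=True, max_examples=50)
@given(
    st.lists(st.floats(-50, 50), min_size=2, max_size=40),
    st.data(),
)
def test_rank_mean_is_half_and_ranks_interior(wealth, data):
    weights = data.draw(
        st.lists(st.floats(0.1, 20), min_size=len(wealth), max_size=len(wealth))
    )
    w = np.asarray(weights)
    r = fractional_rank(wealth, w)
    assert np.all((r > 0) & (r < 1))
    assert abs(np.sum(w / w.sum() * r) - 0.5) < 1e-10
    # ranks non-decreasing in wealth
    order = np.argsort(wealth)
    assert np.all(np.diff(r[order]) >= -1e-15)


# ---------------------------------------------------------------------------
# CI / ECI point estimates
# ---------------------------------------------------------------------------

def _two_record(pro_rich=True):
    y = np.array([0.0, 1.0]) if pro_rich else np.array([1.0, 0.0])
    return RankedOutcome.from_arrays(y, wealth_score=[1.0, 2.0])


def test_two_record_ci_and_eci():
    ranked = _two_record(pro_rich=True)
    assert ranked.mu == 0.5
    np.testing.assert_allclose(ranked.rank, [0.25, 0.75])
    assert concentration_index(ranked, compute_se=False).value == pytest.approx(0.5, abs=1e-15)
    assert erreygers_index(ranked, compute_se=False).value == pytest.approx(1.0, abs=1e-15)


def test_rank_reversal_flips_sign():
    assert concentration_index(_two_record(False), compute_se=False).value == pytest.approx(
        -0.5, abs=1e-15
    )


def test_constant_outcome_gives_zero_index():
    ranked = RankedOutcome.from_arrays([1, 1, 1, 1], wealth_score=[1, 2, 3, 4])
    assert concentration_index(ranked).value == 0.0
    res = erreygers_index(ranked)
    assert res.value == 0.0 and res.degenerate


def test_zero_mean_outcome_is_undefined():
    ranked = RankedOutcome.from_arrays([0, 0, 0], wealth_score=[1, 2, 3])
    with pytest.raises(UndefinedIndexError):
        concentration_index(ranked)
    with pytest.raises(UndefinedIndexError):
        concentration_curve(ranked)


def test_degenerate_bounds_rejected():
    ranked = RankedOutcome.from_arrays([1.0, 2.0], wealth_score=[0, 1], bounds=(2.0, 2.0))
    with pytest.raises(DegenerateBoundsError):
        erreygers_index(ranked)


@settings(derandomize=True, max_examples=60)
@given(
    st.lists(st.integers(0, 1), min_size=3, max_size=30).filter(lambda y: any(y)),
    st.data(),
)
def test_eci_is_four_mu_ci_for_binary(y, data):
    n = len(y)
    wealth = data.draw(st.lists(st.floats(-5, 5), min_size=n, max_size=n))
    weights = data.draw(st.lists(st.floats(0.2, 5), min_size=n, max_size=n))
    ranked = RankedOutcome.from_arrays(y, wealth, weights)
    ci = concentration_index(ranked, compute_se=False).value
    eci = erreygers_index(ranked, compute_se=False).value
    assert abs(eci - 4.0 * ranked.mu * ci) < 1e-10


def brute_force_ci(y, rank, w):
    """Independent oracle: CI = (1/mu) * sum_i sum_j w_i w_j (y_i-y_j)(R_i-R_j) / 2 * 2
    evaluated in exact rational arithmetic (equal double sum of the weighted
    covariance)."""
    n = len(y)
    wf = [Fraction(x).limit_denominator(10**9) for x in w]
    tot = sum(wf)
    wf = [x / tot for x in wf]
    yf = [Fraction(v) for v in y]
    rf = [Fraction(x).limit_denominator(10**9) for x in rank]
    mu = sum(wi * yi for wi, yi in zip(wf, yf))
    if mu == 0:
        return None
    acc = Fraction(0)
    for i in range(n):
        for j in range(n):
            acc += wf[i] * wf[j] * (yf[i] - yf[j]) * (rf[i] - rf[j])
    return acc / (2 * mu) * 2 / 1  # (2/mu) * cov, cov = double-sum / 2


def test_ci_matches_exact_double_sum_on_all_binary_assignments():
    """Covariance-formula CI equals the exact rational double-sum oracle on
    every binary outcome assignment over 6 equal-weight records."""
    n = 6
    wealth = np.arange(1.0, n + 1)
    w = np.ones(n)
    rank = fractional_rank(wealth, w)
    for mask in range(1, 2**n):
        y = np.array([(mask >> i) & 1 for i in range(n)], dtype=float)
        ranked = RankedOutcome.from_arrays(y, wealth, w)
        expected = brute_force_ci(y, rank, w)
        got = concentration_index(ranked, compute_se=False).value
        assert abs(got - float(expected)) < 1e-12, mask


def test_ci_equals_convenient_regression_slope():
    rng = np.random.default_rng(1234)
    for _ in range(100):
        n = 50
        wealth = rng.normal(size=n)
        w = rng.gamma(4.0, 0.25, size=n)
        y = (rng.random(n) < 0.4).astype(float)
        if y.sum() == 0:
            y[0] = 1.0
        ranked = RankedOutcome.from_arrays(y, wealth, w)
        ci = concentration_index(ranked, compute_se=False).value
        slope = convenient_regression_slope(ranked, "CI")
        assert abs(ci - slope) < 1e-10
        eci = erreygers_index(ranked, compute_se=False).value
        assert abs(eci - convenient_regression_slope(ranked, "ECI")) < 1e-10


# ---------------------------------------------------------------------------
# Invariances
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "transform",
    [lambda x: 2.0 * x + 3.0, np.exp, lambda x: x**3, np.tanh],
    ids=["affine", "exp", "cube", "tanh"],
)
def test_index_invariant_to_monotone_wealth_transform(transform):
    rng = np.random.default_rng(7)
    wealth = rng.normal(size=200)
    w = rng.gamma(4, 0.25, size=200)
    y = (rng.random(200) < 0.3 + 0.3 * (wealth > 0)).astype(float)
    base = erreygers_index(RankedOutcome.from_arrays(y, wealth, w), compute_se=False).value
    moved = erreygers_index(
        RankedOutcome.from_arrays(y, transform(wealth), w), compute_se=False
    ).value
    assert abs(base - moved) < 1e-12


def test_index_invariant_to_weight_rescaling():
    rng = np.random.default_rng(8)
    wealth = rng.normal(size=150)
    w = rng.gamma(4, 0.25, size=150)
    y = (rng.random(150) < 0.5).astype(float)
    a = concentration_index(RankedOutcome.from_arrays(y, wealth, w), compute_se=False).value
    b = concentration_index(
        RankedOutcome.from_arrays(y, wealth, 7.3 * w), compute_se=False
    ).value
    assert abs(a - b) < 1e-12


# ---------------------------------------------------------------------------
# Concentration curve
# ---------------------------------------------------------------------------

def test_constant_outcome_curve_is_diagonal():
    ranked = RankedOutcome.from_arrays(np.ones(10), np.arange(10.0))
    curve = concentration_curve(ranked)
    np.testing.assert_allclose(curve.x, curve.y, atol=1e-15)


def test_pro_rich_curve_below_diagonal():
    curve = concentration_curve(_two_record(pro_rich=True))
    np.testing.assert_allclose(curve.x, [0.0, 0.5, 1.0])
    np.testing.assert_allclose(curve.y, [0.0, 0.0, 1.0])


def test_curve_reflection_under_rank_reversal():
    rng = np.random.default_rng(11)
    wealth = rng.normal(size=50)
    y = (rng.random(50) < 0.5).astype(float)
    y[0] = 1.0
    c1 = concentration_curve(RankedOutcome.from_arrays(y, wealth))
    c2 = concentration_curve(RankedOutcome.from_arrays(y, -wealth))
    # reflecting about the diagonal: (x, y) -> (1-x, 1-y) reversed
    np.testing.assert_allclose(c1.x, 1.0 - c2.x[::-1], atol=1e-12)
    np.testing.assert_allclose(c1.y, 1.0 - c2.y[::-1], atol=1e-12)


def test_curve_endpoints_and_monotonicity():
    rng = np.random.default_rng(12)
    ranked = RankedOutcome.from_arrays(
        (rng.random(100) < 0.4).astype(float), rng.normal(size=100),
        rng.gamma(4, 0.25, size=100),
    )
    curve = concentration_curve(ranked)
    assert curve.x[0] == 0.0 and curve.y[0] == 0.0
    assert curve.x[-1] == 1.0 and curve.y[-1] == 1.0
    assert np.all(np.diff(curve.x) >= 0) and np.all(np.diff(curve.y) >= -1e-15)


def test_curve_index_consistency():
    """1 - 2*AUC of the record-level concentration curve equals CI."""
    rng = np.random.default_rng(13)
    for _ in range(5):
        n = 500
        wealth = rng.normal(size=n)  # continuous: no rank ties
        w = rng.gamma(4, 0.25, size=n)
        y = (rng.random(n) < 0.35).astype(float)
        ranked = RankedOutcome.from_arrays(y, wealth, w)
        ci = concentration_index(ranked, compute_se=False).value
        curve = concentration_curve(ranked)
        assert abs(ci - (1.0 - 2.0 * curve.auc())) < 1e-6


# ---------------------------------------------------------------------------
# Standard errors
# ---------------------------------------------------------------------------

def test_se_zero_for_constant_outcome():
    ranked = RankedOutcome.from_arrays(np.ones(20), np.arange(20.0))
    assert index_standard_error(ranked, index_type="ECI") == 0.0


def test_se_shrinks_by_sqrt2_under_duplication():
    rng = np.random.default_rng(21)
    n = 400
    wealth = rng.normal(size=n)
    w = rng.gamma(4, 0.25, size=n)
    y = (rng.random(n) < 0.4 + 0.2 * (wealth > 0)).astype(float)
    ranked = RankedOutcome.from_arrays(y, wealth, w)
    se1 = index_standard_error(ranked, index_type="ECI")
    ranked2 = RankedOutcome.from_arrays(
        np.tile(y, 2), np.tile(wealth, 2), np.tile(w, 2)
    )
    se2 = index_standard_error(ranked2, index_type="ECI")
    assert se2 / se1 == pytest.approx(1.0 / np.sqrt(2.0), rel=0.03)


def test_se_matches_bootstrap_oracle():
    """Convenient-regression ECI SE within 10% of a 500-replicate bootstrap."""
    rng = np.random.default_rng(31)
    n = 5000
    wealth = rng.normal(size=n)
    y = (rng.random(n) < 0.3 + 0.3 * (wealth > 0)).astype(float)
    ranked = RankedOutcome.from_arrays(y, wealth)
    se = index_standard_error(ranked, index_type="ECI")
    boots = np.empty(500)
    for b in range(500):
        idx = rng.integers(0, n, size=n)
        rb = RankedOutcome.from_arrays(y[idx], wealth[idx])
        boots[b] = erreygers_index(rb, compute_se=False).value
    assert se == pytest.approx(boots.std(ddof=1), rel=0.10)


def test_cluster_robust_requires_multiple_psus():
    from ineqdecomp.survey_data import DegenerateVarianceError

    ranked = RankedOutcome.from_arrays(
        [0, 1, 0, 1], wealth_score=[1, 2, 3, 4], psu=["a", "a", "a", "a"]
    )
    with pytest.raises(DegenerateVarianceError):
        index_standard_error(ranked, method="cluster_robust")
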