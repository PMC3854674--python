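import math

import numpy as np
import pytest

from twovar import (
    ProbabilityTable,
    calibrated_q,
    enumerate_last_step_probability,
    f_calibrated,
    f_linear,
    f_type1,
    f_type2,
    mc_last_step_probability,
    mc_probability_curve,
)

CLOSED_FORMS = [
    ("linear", lambda X, L, n: f_linear(X, L, n)),
    ("type1_q05", lambda X, L, n: f_type1(X, L, n, 0.5)),
    ("type1_q3", lambda X, L, n: f_type1(X, L, n, 3.0)),
    ("type1_slope", lambda X, L, n: f_type1(X, L, n, 1.0, form="slope")),
    ("type2_q05", lambda X, L, n: f_type2(X, L, n, 0.5)),
    ("type2_q4", lambda X, L, n: f_type2(X, L, n, 4.0)),
    ("calibrated", lambda X, L, n: f_calibrated(X, L, n)),
]


@pytest.mark.parametrize("name, f", CLOSED_FORMS, ids=[c[0] for c in CLOSED_FORMS])
@pytest.mark.parametrize("n, X", [(2, 1), (5, 3), (8, 15)])
def test_closed_forms_exact_endpoints(name, f, n, X):
    """Every candidate is exactly 1 at L = X and exactly 0 at L = nX."""
    assert f(X, X, n) == 1.0
    assert f(X, n * X, n) == 0.0


@pytest.mark.parametrize("name, f", CLOSED_FORMS, ids=[c[0] for c in CLOSED_FORMS])
def test_closed_forms_non_increasing_in_L(name, f):
    n, X = 6, 7
    vals = [f(X, L, n) for L in range(X, n * X + 1)]
    assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))
    assert all(0.0 <= v <= 1.0 for v in vals)


def test_q_equal_one_reduces_to_linear():
    n, X = 7, 4
    for L in range(X, n * X + 1):
        lin = f_linear(X, L, n)
        assert f_type1(X, L, n, 1.0) == pytest.approx(lin)
        assert f_type2(X, L, n, 1.0) == pytest.approx(lin)
        assert f_type1(X, L, n, 1.0, form="slope") == pytest.approx(lin)


def test_direct_evaluations():
    assert f_linear(15, 67, 8) == pytest.approx(1 - 52 / 105)
    assert f_type2(15, 67, 8, 3.91) == pytest.approx((1 - 52 / 105) ** 3.91)
    assert f_type1(15, 67, 8, 0.31) == pytest.approx(1 - (52 / 105) ** 0.31)
    assert calibrated_q(9) == pytest.approx(4.1929)
    assert f_calibrated(10, 50, 9) == pytest.approx((1 - 0.5) ** 4.1929)


@pytest.mark.parametrize(
    "fn, args",
    [
        (f_linear, (3, 4, 1)),          # n = 1 has no excess-length scale
        (f_type1, (3, 5, 4, 0.0)),      # q must be positive
        (f_type2, (3, 5, 4, -1.0)),
        (f_linear, (3, 2, 4)),          # L < X
        (f_linear, (3, 13, 4)),         # L > nX
    ],
)
def test_closed_form_invalid_arguments(fn, args):
    with pytest.raises(ValueError):
        fn(*args)


# ---------------------------------------------------------------------------
# Monte-Carlo estimator and enumeration oracle
# ---------------------------------------------------------------------------

def test_enumeration_hand_cases():
    # one reduction from {2,2} always gives {2,1}: one of two molecules
    # has length 1, so f = 1 * (1/2)
    assert enumerate_last_step_probability(2, 2, 3) == pytest.approx(0.5)
    assert enumerate_last_step_probability(4, 3, 3) == 1.0     # L = X
    assert enumerate_last_step_probability(4, 3, 12) == 0.0    # L = nX


def test_mc_endpoints_analytic():
    assert mc_last_step_probability(5, 4, 4, reps=10) == 1.0
    assert mc_last_step_probability(5, 4, 20, reps=10) == 0.0


def test_mc_matches_enumeration_small_instances():
    """Monte-Carlo agrees with the exact multiset DP within 3 standard errors."""
    reps = 100_000
    for n in (2, 3, 4):
        for X in (1, 2, 3, 5):
            for L in range(X, n * X + 1):
                exact = enumerate_last_step_probability(n, X, L)
                est = mc_last_step_probability(n, X, L, reps=reps, seed=n * 100 + X * 10 + L)
                tol = 3 * math.sqrt(max(exact * (1 - exact), 1e-12) / reps) + 1e-3
                assert abs(est - exact) < tol, (n, X, L)


def test_mc_seeded_reproducibility():
    a = mc_last_step_probability(6, 4, 13, reps=5000, seed=7)
    b = mc_last_step_probability(6, 4, 13, reps=5000, seed=7)
    c = mc_last_step_probability(6, 4, 13, reps=5000, seed=8)
    assert a == b
    assert a != c


def test_rejection_sampler_agrees_with_eligible_draw():
    """The literal redraw loop has the same law as the eligible-set draw."""
    n, X, L, reps = 3, 3, 6, 20_000
    exact = enumerate_last_step_probability(n, X, L)
    est = mc_last_step_probability(n, X, L, reps=reps, seed=11, sampler="rejection")
    tol = 4 * math.sqrt(exact * (1 - exact) / reps) + 1e-3
    assert abs(est - exact) < tol


def test_mc_curve_matches_single_L_law():
    """The one-sweep curve is unbiased for each L (checked against the DP)."""
    table = mc_probability_curve(3, 4, reps=60_000, seed=3)
    for L in range(4, 13):
        exact = enumerate_last_step_probability(3, 4, L)
        tol = 4 * math.sqrt(max(exact * (1 - exact), 1e-12) / table.reps) + 1e-3
        assert abs(table.values[L] - exact) < tol


def test_mc_invalid_arguments():
    with pytest.raises(ValueError):
        mc_last_step_probability(3, 2, 1)       # L < X
    with pytest.raises(ValueError):
        mc_last_step_probability(3, 2, 7)       # L > nX
    with pytest.raises(ValueError):
        mc_last_step_probability(3, 2, 4, reps=0)


def test_enumeration_state_space_guard():
    with pytest.raises(RuntimeError):
        enumerate_last_step_probability(8, 15, 60, max_states=10)


# ---------------------------------------------------------------------------
# Probability table container
# ---------------------------------------------------------------------------

def test_table_roundtrip_and_completeness(tmp_path):
    table = mc_probability_curve(4, 3, reps=2000, seed=5)
    assert table.is_complete()
    path = tmp_path / "table.csv"
    table.to_csv(path)
    back = ProbabilityTable.from_csv(path)
    assert back == table


def test_table_missing_L_error():
    table = ProbabilityTable(n=3, X=2, values={2: 1.0, 6: 0.0}, reps=1, seed=0)
    assert not table.is_complete()
    with pytest.raises(KeyError, match="3"):
        table.f_array(np.arange(2, 7))


def test_table_rejects_bad_endpoints():
    with pytest.raises(ValueError):
        ProbabilityTable(n=3, X=2, values={2: 0.9}, reps=1, seed=0)
    with pytest.raises(ValueError):
        ProbabilityTable(n=3, X=2, values={6: 0.2}, reps=1, seed=0)
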