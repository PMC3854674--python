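import numpy as np
import pytest

from twovar import (
    ChainSpec,
    DetailedState,
    ProbabilityTable,
    average_q,
    calibrate_mc_route,
    decay_time_grid,
    default_q_grid,
    detailed_chain_survival,
    f_type2,
    fit_optimal_q,
    fit_optimal_q_ode,
    ode_detailed_solve,
    ode_twovar_solve,
    regress_qbar,
    twovar_rk4_grid,
)


def table_from_type2(n, X, q):
    L = np.arange(X, n * X + 1)
    vals = {int(l): float(f_type2(X, int(l), n, q)) for l in L}
    vals[X], vals[n * X] = 1.0, 0.0
    return ProbabilityTable(n=n, X=X, values=vals, reps=0, seed=0, method="exact_enumeration")


def test_fit_recovers_generating_q_exactly():
    table = table_from_type2(6, 8, 2.50)
    q_opt, disc = fit_optimal_q(6, 8, "type2", default_q_grid(), table)
    assert q_opt == 2.50
    assert disc == pytest.approx(0.0, abs=1e-20)


def test_fit_requires_complete_reference():
    table = table_from_type2(4, 3, 2.0)
    del table.values[7]
    with pytest.raises(KeyError, match="7"):
        fit_optimal_q(4, 3, "type2", default_q_grid(), table)


def test_fit_rejects_bad_grid():
    table = table_from_type2(4, 3, 2.0)
    with pytest.raises(ValueError):
        fit_optimal_q(4, 3, "type2", [], table)
    with pytest.raises(ValueError):
        fit_optimal_q(4, 3, "type2", [2.0, 1.0], table)
    with pytest.raises(ValueError):
        fit_optimal_q(4, 3, "nope", [1.0, 2.0], table)


def test_average_q():
    per = {(5, 3): (2.0, 0.1), (5, 4): (3.0, 0.1), (7, 3): (9.0, 0.1)}
    assert average_q(per, 5) == pytest.approx(2.5)
    assert average_q(per, 7) == pytest.approx(9.0)
    with pytest.raises(ValueError):
        average_q(per, 6)


def test_regress_qbar_exact_line():
    pts = [(n, 0.5 * n) for n in (3, 7, 11, 15)]
    slope, intercept = regress_qbar(pts)
    assert slope == pytest.approx(0.5)
    assert intercept == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        regress_qbar([(3, 1.0)])
    with pytest.raises(ValueError):
        regress_qbar([(3, 1.0), (3, 2.0)])


# ---------------------------------------------------------------------------
# Detailed chain ODE
# ---------------------------------------------------------------------------

def test_detailed_ode_initial_and_single_step():
    chain = ChainSpec(n=1, rates=(0.7,))
    times = np.linspace(0, 5, 20)
    sol = ode_detailed_solve(chain, DetailedState(counts=(50,)), times)
    assert sol[0, 0] == pytest.approx(50.0)
    np.testing.assert_allclose(sol[:, 0], 50 * np.exp(-0.7 * times), rtol=1e-6)


def test_detailed_ode_matches_poisson_closed_form():
    """Equal rates, all mass in B1: B_j(t) = X0 e^{-kt}(kt)^{j-1}/(j-1)!."""
    n, k, X0 = 5, 1.3, 100.0
    chain = ChainSpec.equal_rates(n, k)
    times = np.linspace(0, 8, 40)
    sol = ode_detailed_solve(chain, DetailedState(counts=(100, 0, 0, 0, 0)), times)
    import math

    for j in range(n):
        expected = X0 * np.exp(-k * times) * (k * times) ** j / math.factorial(j)
        np.testing.assert_allclose(sol[:, j], expected, atol=1e-6)
    # lumped survival matches the Erlang closed form
    np.testing.assert_allclose(
        sol[:, :n].sum(axis=1), detailed_chain_survival(n, k, X0, times), atol=1e-6
    )


def test_lumped_balance_along_detailed_solution():
    """dX/dt = -k_n B_n and, with equal rates, dL/dt = -k X along solutions."""
    n, k = 4, 0.9
    chain = ChainSpec.equal_rates(n, k)
    times = np.linspace(0, 6, 2001)
    sol = ode_detailed_solve(chain, DetailedState(counts=(30, 5, 2, 0)), times)
    lengths = np.arange(n, 0, -1)
    X = sol[:, :n].sum(axis=1)
    L = sol[:, :n] @ lengths
    h = times[1] - times[0]
    dX = np.gradient(X, h)
    dL = np.gradient(L, h)
    interior = slice(5, -5)
    np.testing.assert_allclose(dX[interior], -k * sol[interior, n - 1], atol=1e-3)
    np.testing.assert_allclose(dL[interior], -k * X[interior], atol=1e-3)


# ---------------------------------------------------------------------------
# Two-variable ODE
# ---------------------------------------------------------------------------

def test_twovar_ode_minimal_length_is_exponential():
    """At L0 = X0 the bracket stays ~1 and X decays like the one-step model."""
    times = np.linspace(0, 5, 30)
    X, L = ode_twovar_solve(6, 1.0, 3.0, 40.0, 40.0, times)
    np.testing.assert_allclose(X, 40 * np.exp(-times), rtol=1e-5)


def test_twovar_ode_monotone_and_validated():
    times = np.linspace(0, 10, 50)
    X, L = ode_twovar_solve(5, 0.5, 2.5, 20.0, 70.0, times)
    assert np.all(np.diff(X) <= 1e-9)
    assert np.all(np.diff(L) <= 1e-9)
    assert np.all(L - X >= -1e-6)
    with pytest.raises(ValueError):
        ode_twovar_solve(5, 0.5, 2.5, 20.0, 10.0, times)     # L0 < X0
    with pytest.raises(ValueError):
        ode_twovar_solve(5, 0.5, 2.5, 20.0, 200.0, times)    # L0 > nX0
    with pytest.raises(ValueError):
        ode_twovar_solve(5, 0.5, -1.0, 20.0, 70.0, times)    # bad q


@pytest.mark.parametrize("q", [0.5, 3.0, 10.0])
def test_rk4_grid_matches_adaptive_solver(q):
    n, k, X0 = 5, 1.0, 100.0
    times = decay_time_grid(n, k)
    X_ref, _ = ode_twovar_solve(n, k, q, X0, n * X0, times)
    X_rk4 = twovar_rk4_grid(n, k, X0, n * X0, times, np.array([q]))[:, 0]
    assert np.abs(X_rk4 - X_ref).max() < 1e-4


def test_decay_time_grid_covers_full_decay():
    for n in (3, 9, 15, 20):
        grid = decay_time_grid(n, 0.7)
        assert detailed_chain_survival(n, 0.7, 1.0, grid[-1:])[0] <= 1.01e-4
        assert grid[0] == 0.0 and grid.size == 200


def test_fit_optimal_q_ode_degenerate_single_step():
    q_opt, disc = fit_optimal_q_ode(1, 50.0, q_grid=np.array([0.3, 1.0, 4.0]))
    assert q_opt == 0.3
    assert disc == 0.0


def test_ode_route_optimum_independent_of_copy_number():
    """The two-variable ODE scales linearly in X0, so q_opt is X0-free."""
    grid = np.round(np.arange(20, 81) * 0.1, 1)  # coarse grid for speed
    q_small, _ = fit_optimal_q_ode(5, 5.0, q_grid=grid)
    q_large, _ = fit_optimal_q_ode(5, 500.0, q_grid=grid)
    assert q_small == q_large


# ---------------------------------------------------------------------------
# Route drivers
# ---------------------------------------------------------------------------

def test_mc_route_trends():
    """q_bar grows with n; at fixed n the optimum varies weakly with X."""
    cal = calibrate_mc_route(
        n_values=(3, 6, 10), X_values=(5, 10, 15), reps=3000, seed=42
    )
    qb = cal.q_bar
    assert qb[3] < qb[6] < qb[10]
    for n in (3, 6, 10):
        qs = [q for (nn, _), (q, _) in cal.per_condition.items() if nn == n]
        assert np.std(qs) / np.mean(qs) < 0.15
    slope, intercept = cal.regression
    assert slope > 0


def test_mc_route_deterministic_given_seed():
    a = calibrate_mc_route(n_values=(3,), X_values=(4, 5), reps=500, seed=9)
    b = calibrate_mc_route(n_values=(3,), X_values=(4, 5), reps=500, seed=9)
    assert a.per_condition == b.per_condition


def test_calibration_serialization(tmp_path):
    cal = calibrate_mc_route(n_values=(3, 4), X_values=(3, 4), reps=300, seed=1)
    df = cal.to_frame()
    assert set(df.columns) == {"n", "X", "family", "route", "q_opt", "discrepancy"}
    assert len(df) == 4
    out = tmp_path / "cal.json"
    cal.to_json(out)
    import json

    payload = json.loads(out.read_text())
    assert payload["route"] == "monte_carlo"
    assert payload["regression"] is not None
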