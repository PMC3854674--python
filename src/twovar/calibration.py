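"""Calibration of the Type I/II exponent q against reference dynamics.

Two independent routes are implemented:

* the **stochastic route**: for each condition (n, X), grid-search the q that
  best matches the Monte-Carlo reference probabilities f(X, L, n) over the
  full integer L grid; average the optima over X at each n; regress the
  averages on n by ordinary least squares.

* the **ODE route**: for each (n, X0), solve the detailed equal-rate chain
  ODE (all mass initially in B1) and the two-variable ODE

      dX/dt = -k X f(X, L, n),     dL/dt = -k X,
      f = (1 - (L - X)/(X(n-1)))^q,

  and pick the q whose X(t) is closest in least squares over a uniform time
  grid spanning the full decay.

With equal rates the detailed chain has the closed-form solution
B_j(t) = B_1(0) e^{-kt} (kt)^{j-1}/(j-1)!, so the surviving total is
X(t) = X0 * P(Poisson(kt) <= n-1) — an Erlang survival function.  The time
horizon is therefore chosen as the 1e-4 survival quantile of Erlang(n, k),
which covers > 99.99% of the decay for every n.

The default discrepancy metric is the sum of squared differences; the sum of
absolute differences is available for sensitivity checks (``metric="abs"``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import solve_ivp

from .core import ChainSpec, DetailedState
from .probability import DEFAULT_REPS, ProbabilityTable, mc_probability_curve

__all__ = [
    "QCalibration",
    "default_q_grid",
    "fit_optimal_q",
    "average_q",
    "regress_qbar",
    "ode_detailed_solve",
    "detailed_chain_survival",
    "ode_twovar_solve",
    "twovar_rk4_grid",
    "decay_time_grid",
    "fit_optimal_q_ode",
    "calibrate_mc_route",
    "calibrate_ode_route",
    "MC_N_RANGE",
    "MC_X_RANGE",
    "ODE_N_VALUES",
    "ODE_X0_VALUES",
]

# Calibration grids: the stochastic route scans n and X over 3..20; the ODE
# route uses three chain lengths and six initial copy numbers.
MC_N_RANGE = tuple(range(3, 21))
MC_X_RANGE = tuple(range(3, 21))
ODE_N_VALUES = (5, 10, 15)
ODE_X0_VALUES = (5, 10, 50, 100, 200, 500)


def default_q_grid() -> np.ndarray:
    """The q search grid 0.01, 0.02, ..., 15.00."""
    return np.round(np.arange(1, 1501) * 0.01, 2)


def _family_values(family: str, n: int, X: int, L: np.ndarray, q_grid: np.ndarray) -> np.ndarray:
    """Candidate f values, shape (len(q_grid), len(L))."""
    r = (L.astype(float) - X) / (X * (n - 1))
    if family == "type1":
        F = 1.0 - r[None, :] ** q_grid[:, None]
    elif family == "type2":
        F = (1.0 - r[None, :]) ** q_grid[:, None]
    else:
        raise ValueError(f"unknown family {family!r}")
    return F


def fit_optimal_q(
    n: int,
    X: int,
    family: str,
    q_grid: Sequence[float],
    reference: ProbabilityTable,
    metric: str = "sse",
) -> tuple[float, float]:
    """Grid-search the q minimizing the discrepancy to a reference table.

    The discrepancy is summed over every integer L in [X, nX]; ties are broken
    toward the smaller q.  Returns ``(q_opt, attained_discrepancy)``.
    """
    q_grid = np.asarray(q_grid, dtype=float)
    if q_grid.size == 0:
        raise ValueError("q_grid must be non-empty")
    if np.any(np.diff(q_grid) <= 0):
        raise ValueError("q_grid must be strictly ascending")
    L = np.arange(X, n * X + 1)
    ref = reference.f_array(L)  # raises KeyError naming missing L values
    F = _family_values(family, n, X, L, q_grid)
    dev = np.abs(F - ref[None, :])
    if metric == "sse":
        disc = (dev ** 2).sum(axis=1)
    elif metric == "abs":
        disc = dev.sum(axis=1)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    i = int(np.argmin(disc))  # argmin returns the first (smallest-q) minimum
    return float(q_grid[i]), float(disc[i])


def average_q(per_condition: dict[tuple[int, int], tuple[float, float]], n: int) -> float:
    """Arithmetic mean of the optimal q over the X values calibrated at n."""
    qs = [q for (nn, _), (q, _) in per_condition.items() if nn == n]
    if not qs:
        raise ValueError(f"no calibrated conditions at n = {n}")
    return float(np.mean(qs))


def regress_qbar(points: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Ordinary least-squares line q_bar = slope * n + intercept."""
    pts = list(points)
    ns = np.array([p[0] for p in pts], dtype=float)
    qs = np.array([p[1] for p in pts], dtype=float)
    if len(pts) < 2 or np.all(ns == ns[0]):
        raise ValueError("need at least two distinct n values")
    res = stats.linregress(ns, qs)
    return float(res.slope), float(res.intercept)


# ---------------------------------------------------------------------------
# ODE solvers
# ---------------------------------------------------------------------------

def ode_detailed_solve(
    chain: ChainSpec,
    initial: DetailedState,
    times: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Solve the detailed chain rate equations.

    dB1/dt = -k1 B1,  dBi/dt = k_{i-1} B_{i-1} - k_i B_i,  dP/dt = k_n B_n.

    Returns an array of shape ``(len(times), n + 1)``: columns B1..Bn, P.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0 or times[0] != 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be ascending and start at 0")
    if initial.n != chain.n:
        raise ValueError("initial state does not match the chain size")
    k = np.asarray(chain.rates)
    n = chain.n

    def rhs(t, y):
        b = y[:n]
        flux = k * b
        dy = np.empty(n + 1)
        dy[0] = -flux[0]
        dy[1:n] = flux[: n - 1] - flux[1:n]
        dy[n] = flux[n - 1]
        return dy

    y0 = np.array(list(initial.counts) + [initial.product], dtype=float)
    sol = solve_ivp(rhs, (times[0], times[-1]), y0, t_eval=times,
                    method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"detailed ODE solve failed: {sol.message}")
    return sol.y.T


def detailed_chain_survival(n: int, k: float, X0: float, times: np.ndarray) -> np.ndarray:
    """Closed-form X(t) for an equal-rate chain started with all mass in B1.

    X(t) = X0 * P(Poisson(k t) <= n - 1): the Erlang(n, k) survival function
    scaled by the initial count.
    """
    return X0 * stats.poisson.cdf(n - 1, k * np.asarray(times, dtype=float))


def _twovar_f(X: np.ndarray, L: np.ndarray, n: int, q) -> np.ndarray:
    if n == 1:
        return np.ones_like(np.asarray(X, dtype=float))
    Xs = np.maximum(X, 1e-12)
    r = np.clip((L - X) / (Xs * (n - 1)), 0.0, 1.0)
    return (1.0 - r) ** q


def ode_twovar_solve(
    n: int,
    k: float,
    q: float,
    X0: float,
    L0: float,
    times: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
    floor: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the two-variable ODE dX/dt = -kX f, dL/dt = -kX.

    The state is frozen once X falls below ``floor`` (the excess ratio becomes
    0/0 at extinction).  Returns ``(X(t), L(t))`` on the requested grid.
    """
    times = np.asarray(times, dtype=float)
    if X0 <= 0:
        raise ValueError("X0 must be positive")
    if not (X0 <= L0 <= n * X0):
        raise ValueError(f"L0 must lie in [X0, n*X0] = [{X0}, {n * X0}]")
    if times.size == 0 or times[0] != 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be ascending and start at 0")
    if q <= 0:
        raise ValueError("q must be positive")

    def rhs(t, y):
        X, L = y
        if X <= floor:
            return [0.0, 0.0]
        f = float(_twovar_f(np.array(X), np.array(L), n, q))
        return [-k * X * f, -k * X]

    sol = solve_ivp(rhs, (times[0], times[-1]), [float(X0), float(L0)],
                    t_eval=times, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"two-variable ODE solve failed: {sol.message}")
    return sol.y[0], sol.y[1]


def twovar_rk4_grid(
    n: int,
    k: float,
    X0: float,
    L0: float,
    times: np.ndarray,
    q_values: np.ndarray,
    substeps: int = 40,
    floor: float = 1e-9,
) -> np.ndarray:
    """X(t) of the two-variable ODE for every q at once (classical RK4).

    Fixed-step fourth-order Runge-Kutta on the uniform grid ``times`` with
    ``substeps`` internal steps per interval, vectorized across ``q_values``.
    The system is a smooth two-dimensional decay, so the fixed-step solution
    matches the adaptive stiff solver to ~1e-6 relative accuracy while being
    orders of magnitude faster over a 1500-point q grid.

    Returns an array of shape ``(len(times), len(q_values))``.
    """
    q_values = np.asarray(q_values, dtype=float)
    times = np.asarray(times, dtype=float)
    h_grid = np.diff(times)
    if not np.allclose(h_grid, h_grid[0]):
        raise ValueError("times must be uniform for the fixed-step integrator")
    m = q_values.size
    X = np.full(m, float(X0))
    L = np.full(m, float(L0))
    out = np.empty((times.size, m))
    out[0] = X
    h = h_grid[0] / substeps

    def rhs(Xv, Lv):
        alive = Xv > floor
        f = _twovar_f(Xv, Lv, n, q_values)
        dX = -k * Xv * f * alive
        dL = -k * Xv * alive
        return dX, dL

    for i in range(1, times.size):
        for _ in range(substeps):
            k1x, k1l = rhs(X, L)
            k2x, k2l = rhs(X + 0.5 * h * k1x, L + 0.5 * h * k1l)
            k3x, k3l = rhs(X + 0.5 * h * k2x, L + 0.5 * h * k2l)
            k4x, k4l = rhs(X + h * k3x, L + h * k3l)
            X = X + (h / 6.0) * (k1x + 2 * k2x + 2 * k3x + k4x)
            L = L + (h / 6.0) * (k1l + 2 * k2l + 2 * k3l + k4l)
        out[i] = X
    return out


def decay_time_grid(n: int, k: float, npoints: int = 200, tail: float = 1e-4) -> np.ndarray:
    """Uniform grid [0, T] with T the Erlang(n, k) survival quantile at ``tail``.

    By T, a fraction 1 - tail of the molecules of an equal-rate n-step chain
    have completed all steps, so the grid spans the entire decay at any n.
    """
    T = float(stats.gamma.isf(tail, n) / k)
    return np.linspace(0.0, T, npoints)


def fit_optimal_q_ode(
    n: int,
    X0: float,
    q_grid: Sequence[float] | None = None,
    k: float = 1.0,
    times: np.ndarray | None = None,
    metric: str = "sse",
) -> tuple[float, float]:
    """Optimal q matching the two-variable ODE to the detailed equal-rate chain.

    The detailed reference starts with all X0 molecules in B1 (so L0 = n X0)
    and uses the closed-form Erlang survival solution; the two-variable model
    is integrated for every q on the grid and the summed squared difference of
    X(t) over the time grid is minimized (ties toward smaller q).
    """
    if X0 <= 0:
        raise ValueError("X0 must be positive")
    q_grid = default_q_grid() if q_grid is None else np.asarray(q_grid, dtype=float)
    if np.any(np.diff(q_grid) <= 0):
        raise ValueError("q_grid must be strictly ascending")
    if times is None:
        times = decay_time_grid(n, k)
    ref = detailed_chain_survival(n, k, X0, times)
    if n == 1:
        # No intermediate states: the two-variable model is exact for any q.
        return float(q_grid[0]), 0.0
    Xq = twovar_rk4_grid(n, k, X0, n * X0, times, q_grid)
    dev = np.abs(Xq - ref[:, None])
    disc = (dev ** 2).sum(axis=0) if metric == "sse" else dev.sum(axis=0)
    i = int(np.argmin(disc))
    return float(q_grid[i]), float(disc[i])


# ---------------------------------------------------------------------------
# Calibration container and route drivers
# ---------------------------------------------------------------------------

@dataclass
class QCalibration:
    """Per-condition optimal q values, per-n averages and the q_bar(n) line."""

    family: str
    route: str                                   # "monte_carlo" | "ode"
    q_grid: np.ndarray
    per_condition: dict[tuple[int, int], tuple[float, float]]
    q_bar: dict[int, float] = field(default_factory=dict)
    regression: tuple[float, float] | None = None

    def finalize(self) -> "QCalibration":
        ns = sorted({n for n, _ in self.per_condition})
        self.q_bar = {n: average_q(self.per_condition, n) for n in ns}
        if len(ns) >= 2:
            self.regression = regress_qbar(list(self.q_bar.items()))
        return self

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"n": n, "X": X, "family": self.family, "route": self.route,
             "q_opt": q, "discrepancy": d}
            for (n, X), (q, d) in sorted(self.per_condition.items())
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "family": self.family,
            "route": self.route,
            "q_grid": {"min": float(self.q_grid[0]), "max": float(self.q_grid[-1]),
                       "size": int(self.q_grid.size)},
            "per_condition": [
                {"n": n, "X": X, "q_opt": q, "discrepancy": d}
                for (n, X), (q, d) in sorted(self.per_condition.items())
            ],
            "q_bar": {str(n): q for n, q in self.q_bar.items()},
            "regression": (
                None if self.regression is None
                else {"slope": self.regression[0], "intercept": self.regression[1]}
            ),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _condition_seed(base_seed: int, n: int, X: int) -> int:
    """Deterministic per-condition seed below 2**31."""
    return int(np.random.SeedSequence([base_seed, n, X]).generate_state(1)[0] % (2 ** 31))


def calibrate_mc_route(
    n_values: Iterable[int] = MC_N_RANGE,
    X_values: Iterable[int] = MC_X_RANGE,
    family: str = "type2",
    q_grid: Sequence[float] | None = None,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
    metric: str = "sse",
    progress: Callable[[int, int], None] | None = None,
) -> QCalibration:
    """Stochastic-route calibration over a grid of (n, X) conditions."""
    q_grid = default_q_grid() if q_grid is None else np.asarray(q_grid, dtype=float)
    per: dict[tuple[int, int], tuple[float, float]] = {}
    for n in n_values:
        for X in X_values:
            table = mc_probability_curve(n, X, reps=reps, seed=_condition_seed(seed, n, X))
            per[(n, X)] = fit_optimal_q(n, X, family, q_grid, table, metric=metric)
            if progress is not None:
                progress(n, X)
    return QCalibration(family=family, route="monte_carlo", q_grid=q_grid,
                        per_condition=per).finalize()


def calibrate_ode_route(
    n_values: Iterable[int] = ODE_N_VALUES,
    X0_values: Iterable[int] = ODE_X0_VALUES,
    q_grid: Sequence[float] | None = None,
    k: float = 1.0,
    metric: str = "sse",
) -> QCalibration:
    """ODE-route calibration (Type II family) over (n, X0) conditions."""
    q_grid = default_q_grid() if q_grid is None else np.asarray(q_grid, dtype=float)
    per: dict[tuple[int, int], tuple[float, float]] = {}
    for n in n_values:
        for X0 in X0_values:
            per[(n, X0)] = fit_optimal_q_ode(n, X0, q_grid=q_grid, k=k, metric=metric)
    return QCalibration(family="type2", route="ode", q_grid=q_grid,
                        per_condition=per).finalize()
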