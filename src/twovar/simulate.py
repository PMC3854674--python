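"""Exact and lumped stochastic simulation of multi-step reaction chains.

``ssa_detailed`` runs the Gillespie direct method on the full chain: waiting
time tau = ln(1/r1)/a0, channel selected by cumulative propensity against
r2*a0, propensities a_i = k_i [B_i] (plus an optional zero-order synthesis
channel injecting full-length molecules).

``ssa_twovar`` replaces the whole chain by a single lumped channel with
propensity a = k X (k the harmonic-mean rate).  When that channel fires, an
extra uniform draw r3 decides which lumped transition occurs:

    r3 <= f(X, L, n):  (X, L) -> (X - 1, L - 1)   (the last step fired)
    r3 >  f(X, L, n):  (X, L) -> (X,     L - 1)   (an interior step fired)

(the measure-zero tie r3 = f is assigned to the degradation branch).  Every
event decreases L by exactly 1, preserving X <= L <= nX.

``ensemble`` aggregates many seeded runs onto a shared time grid by
last-value-carried-forward sampling and reports pointwise mean and variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core import ChainSpec, DetailedState

__all__ = [
    "Trajectory",
    "EnsembleSummary",
    "ssa_detailed",
    "ssa_twovar",
    "ensemble",
    "sample_onto_grid",
]


@dataclass
class Trajectory:
    """Event-resolved trajectory of a stochastic simulation.

    ``times`` are post-event times starting at 0; ``X`` and ``L`` are the
    lumped observables after each event.  For detailed runs, ``species``
    holds the per-species counts (columns B1..Bn, P); for two-variable runs,
    ``branches`` optionally logs, per firing of the lumped channel, whether
    the degradation branch was taken.
    """

    model: str                       # "detailed" | "twovar"
    times: np.ndarray
    X: np.ndarray
    L: np.ndarray
    seed: int
    species: np.ndarray | None = None
    branches: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.times[0] != 0:
            raise ValueError("trajectory must start at time 0")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be ascending")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.times, "X": self.X, "L": self.L})
        if self.species is not None:
            n = self.species.shape[1] - 1
            for j in range(n):
                df[f"B{j + 1}"] = self.species[:, j]
            df["P"] = self.species[:, n]
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class EnsembleSummary:
    """Pointwise mean and variance of X over a seeded ensemble of runs."""

    times: np.ndarray
    mean_X: np.ndarray
    var_X: np.ndarray
    n_runs: int
    base_seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "mean_X": self.mean_X, "var_X": self.var_X}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def ssa_detailed(
    chain: ChainSpec,
    initial: DetailedState,
    t_end: float,
    seed: int | None = None,
    synthesis_rate: float = 0.0,
    max_events: int | None = None,
) -> Trajectory:
    """Gillespie direct-method trajectory of the detailed chain.

    Terminates at ``t_end`` or when all propensities vanish.  Each firing of
    step i moves one molecule Bi -> Bi+1 (or Bn -> P); the optional zero-order
    synthesis channel injects a molecule into B1.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if initial.n != chain.n:
        raise ValueError("initial state does not match the chain size")
    n = chain.n
    rates = chain.rates
    rng = np.random.default_rng(seed)
    counts = list(initial.counts)
    product = initial.product

    t = 0.0
    times = [0.0]
    states = [counts + [product]]
    n_events = 0
    while True:
        a = [rates[i] * counts[i] for i in range(n)]
        if synthesis_rate > 0:
            a.append(synthesis_rate)
        a0 = sum(a)
        if a0 == 0.0:
            break
        t += np.log(1.0 / rng.random()) / a0
        if t > t_end:
            break
        target = rng.random() * a0
        acc = 0.0
        ch = len(a) - 1
        for i, ai in enumerate(a):
            acc += ai
            if target <= acc:
                ch = i
                break
        if ch == n:                       # synthesis
            counts[0] += 1
        elif ch == n - 1:                 # last step: Bn -> P
            counts[n - 1] -= 1
            if chain.product_absorbing:
                product += 1
        else:                             # interior conversion
            counts[ch] -= 1
            counts[ch + 1] += 1
        times.append(t)
        states.append(counts + [product])
        n_events += 1
        if max_events is not None and n_events >= max_events:
            break

    species = np.array(states, dtype=np.int64)
    lengths = np.arange(n, 0, -1)
    X = species[:, :n].sum(axis=1)
    L = species[:, :n] @ lengths
    return Trajectory(
        model="detailed",
        times=np.array(times),
        X=X,
        L=L,
        seed=-1 if seed is None else int(seed),
        species=species,
    )


def ssa_twovar(
    n: int,
    k: float,
    X0: int,
    L0: int,
    f: Callable[[int, int, int], float],
    t_end: float,
    seed: int | None = None,
    synthesis_rate: float = 0.0,
    record_branches: bool = False,
) -> Trajectory:
    """Modified SSA with the lumped two-variable channel (Algorithm II).

    Per event, three uniform draws are consumed in order: r1 (waiting time),
    r2 (channel), and — when the lumped channel fired — r3 (branch).  The
    probability function ``f`` receives integer (X, L, n) and must return a
    value in [0, 1]; anything else raises a contract-violation error.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if X0 < 0 or (X0 > 0 and not (X0 <= L0 <= n * X0)) or (X0 == 0 and L0 != 0):
        raise ValueError(f"invalid initial lumped state X0={X0}, L0={L0}")
    rng = np.random.default_rng(seed)
    X, L = int(X0), int(L0)
    t = 0.0
    times = [0.0]
    Xs = [X]
    Ls = [L]
    branches: list[bool] = []
    while True:
        a_lump = k * X
        a0 = a_lump + synthesis_rate
        if a0 == 0.0:
            break
        t += np.log(1.0 / rng.random()) / a0
        if t > t_end:
            break
        r2 = rng.random()
        if r2 * a0 <= a_lump:
            fval = f(X, L, n)
            if not (0.0 <= fval <= 1.0):
                raise RuntimeError(
                    f"probability function returned {fval} outside [0, 1] "
                    f"at (X={X}, L={L}, n={n})"
                )
            # Boundary feasibility: a length-1 molecule can only exist when
            # L <= n(X-1) + 1, so the last step cannot fire above that line
            # (approximate f need not vanish there); conversely at L = X every
            # molecule has length 1 and only the last step can fire.  These
            # guards keep X <= L <= nX invariant for any f.
            if L - 1 > n * (X - 1):
                fval = 0.0
            elif L == X:
                fval = 1.0
            r3 = rng.random()
            if r3 <= fval:
                X -= 1
                L -= 1
                if record_branches:
                    branches.append(True)
            else:
                L -= 1
                if record_branches:
                    branches.append(False)
        else:                             # synthesis of a full-length molecule
            X += 1
            L += n
        times.append(t)
        Xs.append(X)
        Ls.append(L)

    return Trajectory(
        model="twovar",
        times=np.array(times),
        X=np.array(Xs, dtype=np.int64),
        L=np.array(Ls, dtype=np.int64),
        seed=-1 if seed is None else int(seed),
        branches=np.array(branches, dtype=bool) if record_branches else None,
    )


def sample_onto_grid(times: np.ndarray, values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Last-value-carried-forward sampling of a piecewise-constant path."""
    idx = np.searchsorted(times, grid, side="right") - 1
    idx = np.clip(idx, 0, len(values) - 1)
    return values[idx]


def ensemble(
    run: Callable[[int], Trajectory],
    n_runs: int,
    grid: Sequence[float],
    base_seed: int = 0,
) -> EnsembleSummary:
    """Mean and variance of X over ``n_runs`` seeded trajectories.

    ``run`` is a closure mapping a seed to a Trajectory; run i receives seed
    ``base_seed + i``.  Trajectories are sampled onto the shared grid by
    last-value-carried-forward and discarded, so memory stays flat for large
    ensembles.  The variance is the population variance over runs.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    grid = np.asarray(grid, dtype=float)
    s1 = np.zeros(grid.size)
    s2 = np.zeros(grid.size)
    for i in range(n_runs):
        traj = run(base_seed + i)
        x = sample_onto_grid(traj.times, traj.X, grid).astype(float)
        s1 += x
        s2 += x * x
    mean = s1 / n_runs
    var = np.maximum(s2 / n_runs - mean ** 2, 0.0)
    return EnsembleSummary(times=grid, mean_X=mean, var_X=var,
                           n_runs=n_runs, base_seed=base_seed)
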