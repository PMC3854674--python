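"""Last-step firing probability f(X, L, n) of a multi-step reaction chain.

Given X molecules with total length L in an n-step chain, f(X, L, n) is the
probability that the next reaction event is the final step Bn -> P.  It is the
quantity that turns the pair of lumped transitions

    (X, L) -> (X,   L-1)   with probability 1 - f   (an interior step fires)
    (X, L) -> (X-1, L-1)   with probability f       (the last step fires)

into a faithful reduction of the full chain.  This module computes f three
ways:

* ``mc_last_step_probability`` — the Monte-Carlo procedure (Algorithm I):
  repeatedly distribute nX - L single-unit length reductions uniformly at
  random over molecules of length > 1 and average the fraction of length-1
  molecules, using the law of total probability
  f = sum_j P(Bn = j | L, X) * j / X.
* ``enumerate_last_step_probability`` — an exact dynamic program over length
  multisets, usable as an independent oracle on small instances.
* ``f_linear`` / ``f_type1`` / ``f_type2`` / ``f_calibrated`` — closed-form
  candidate families in the normalized excess length
  r = (L - X) / (X (n - 1)):

      linear    f = 1 - r
      Type I    f = 1 - r^q
      Type II   f = (1 - r)^q
      calibrated: Type II with q(n) = 0.3146 n + 1.3615.

  All are exactly 1 at L = X (everything has length 1) and exactly 0 at
  L = nX (everything is full length).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ProbabilityTable",
    "mc_last_step_probability",
    "mc_probability_curve",
    "enumerate_last_step_probability",
    "f_linear",
    "f_type1",
    "f_type2",
    "f_calibrated",
    "calibrated_q",
    "Q_VS_N_SLOPE",
    "Q_VS_N_INTERCEPT",
]

#: Stochastic-route calibration line q(n) = slope * n + intercept relating the
#: Type II exponent to the number of reaction steps.
Q_VS_N_SLOPE = 0.3146
Q_VS_N_INTERCEPT = 1.3615

DEFAULT_REPS = 10_000


def _check_XLn(n: int, X: int, L) -> None:
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if X < 1:
        raise ValueError(f"X must be >= 1, got {X}")
    L = np.asarray(L)
    if np.any(L < X) or np.any(L > n * X):
        raise ValueError(f"L must lie in [X, nX] = [{X}, {n * X}]")


def _excess_ratio(X: int, L, n: int):
    """r = (L - X) / (X (n - 1)), the excess length normalized to [0, 1]."""
    if n < 2:
        raise ValueError("n must be >= 2 (a 1-step chain has f identically 1)")
    _check_XLn(n, X, L)
    return (np.asarray(L, dtype=float) - X) / (X * (n - 1))


# ---------------------------------------------------------------------------
# Monte-Carlo estimation (Algorithm I)
# ---------------------------------------------------------------------------

def _mc_length1_curve(n: int, X: int, reps: int, rng: np.random.Generator) -> np.ndarray:
    """Mean fraction of length-1 molecules after m = 0..(n-1)X reductions.

    Each of ``reps`` trials starts from X molecules of full length n and
    applies single-unit reductions, each choosing uniformly among the
    molecules whose length exceeds 1.  Recording the count of length-1
    molecules after every reduction yields the whole f curve in one pass:
    the state after m reductions has the same law as a fresh trial run for
    m reductions.

    Returns an array ``f[m]`` with f[m] = E[#length-1 / X] after m
    reductions, i.e. f at total length L = nX - m.
    """
    # counts[t, j] = number of molecules of length j+1 in trial t
    counts = np.zeros((reps, n), dtype=np.int64)
    counts[:, n - 1] = X
    n_red = (n - 1) * X
    sum_c1 = np.zeros(n_red + 1)
    rows = np.arange(reps)
    for m in range(1, n_red + 1):
        w = counts[:, 1:]                      # eligible: lengths 2..n
        tot = w.sum(axis=1)
        u = rng.random(reps) * tot
        cum = np.cumsum(w, axis=1)
        idx = (u[:, None] >= cum).sum(axis=1)  # chosen length = idx + 2
        counts[rows, idx + 1] -= 1
        counts[rows, idx] += 1
        sum_c1[m] = counts[:, 0].sum()
    return sum_c1 / (reps * X)


def _mc_length1_single_rejection(
    n: int, X: int, m: int, reps: int, rng: np.random.Generator
) -> float:
    """Literal rejection-sampling variant of the reduction step.

    Draws a uniformly random molecule and redraws while its length is 1,
    exactly as the textual procedure states.  Statistically identical to the
    eligible-set draw; kept for fidelity testing on small instances.
    """
    total = 0
    for _ in range(reps):
        lengths = np.full(X, n, dtype=np.int64)
        for _ in range(m):
            while True:
                j = int(rng.integers(X))
                if lengths[j] > 1:
                    lengths[j] -= 1
                    break
        total += int((lengths == 1).sum())
    return total / (reps * X)


def mc_last_step_probability(
    n: int,
    X: int,
    L: int,
    reps: int = DEFAULT_REPS,
    seed: int | None = None,
    sampler: str = "eligible",
) -> float:
    """Monte-Carlo estimate of f(X, L, n) (Algorithm I).

    Each trial applies nX - L uniform single-unit reductions to X full-length
    molecules and records the number of length-1 molecules j; the estimate is
    the average of j / X over trials.  The endpoints L = X (f = 1) and
    L = nX (f = 0) are forced analytically and return without sampling.

    Parameters
    ----------
    sampler : "eligible" draws uniformly over the molecules with length > 1;
        "rejection" redraws over all molecules until an eligible one is hit
        (the literal textual procedure — same law, slower).
    """
    _check_XLn(n, X, L)
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    if L == X:
        return 1.0
    if L == n * X:
        return 0.0
    m = n * X - L
    rng = np.random.default_rng(seed)
    if sampler == "rejection":
        return _mc_length1_single_rejection(n, X, m, reps, rng)
    if sampler != "eligible":
        raise ValueError(f"unknown sampler {sampler!r}")
    counts = np.zeros((reps, n), dtype=np.int64)
    counts[:, n - 1] = X
    rows = np.arange(reps)
    for _ in range(m):
        w = counts[:, 1:]
        tot = w.sum(axis=1)
        u = rng.random(reps) * tot
        cum = np.cumsum(w, axis=1)
        idx = (u[:, None] >= cum).sum(axis=1)
        counts[rows, idx + 1] -= 1
        counts[rows, idx] += 1
    return float(counts[:, 0].sum() / (reps * X))


def mc_probability_curve(
    n: int,
    X: int,
    reps: int = DEFAULT_REPS,
    seed: int | None = None,
) -> "ProbabilityTable":
    """Monte-Carlo f(X, L, n) for every L in [X, nX] in a single sweep.

    One continued reduction pass per trial yields the estimate at every L with
    the same marginal law (and the same per-L variance) as independent per-L
    runs.  Endpoints are exact by construction and forced analytically.
    """
    _check_XLn(n, X, X)
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    rng = np.random.default_rng(seed)
    if n == 1:
        values = {X: 1.0}
    else:
        f_by_m = _mc_length1_curve(n, X, reps, rng)
        Ls = np.arange(X, n * X + 1)
        f = f_by_m[n * X - Ls]
        f[0], f[-1] = 1.0, 0.0
        values = {int(l): float(v) for l, v in zip(Ls, f)}
    return ProbabilityTable(
        n=n, X=X, values=values, reps=reps,
        seed=-1 if seed is None else int(seed), method="monte_carlo",
    )


# ---------------------------------------------------------------------------
# Exact enumeration oracle
# ---------------------------------------------------------------------------

def enumerate_last_step_probability(
    n: int, X: int, L: int, max_states: int = 500_000
) -> float:
    """Exact E[#length-1 molecules / X] under the uniform-reduction process.

    Dynamic program over length multisets (encoded as counts per length):
    from each configuration, every molecule of length > 1 is reduced with
    equal probability.  After exactly nX - L reductions the expected fraction
    of length-1 molecules is returned.  Intended as an independent oracle for
    the Monte-Carlo estimator on small instances.
    """
    _check_XLn(n, X, L)
    if L == X:
        return 1.0
    if L == n * X:
        return 0.0
    m = n * X - L
    start = tuple([0] * (n - 1) + [X])  # counts per length 1..n
    dist: dict[tuple[int, ...], float] = {start: 1.0}
    for _ in range(m):
        new: dict[tuple[int, ...], float] = {}
        for state, p in dist.items():
            eligible = X - state[0]
            for j in range(1, n):          # reduce a molecule of length j+1
                c = state[j]
                if c == 0:
                    continue
                child = list(state)
                child[j] -= 1
                child[j - 1] += 1
                child_t = tuple(child)
                new[child_t] = new.get(child_t, 0.0) + p * c / eligible
        dist = new
        if len(dist) > max_states:
            raise RuntimeError(
                f"state space exceeded {max_states} configurations; "
                "the enumeration oracle is meant for small instances"
            )
    return sum(p * s[0] for s, p in dist.items()) / X


# ---------------------------------------------------------------------------
# Closed-form candidate families
# ---------------------------------------------------------------------------

def f_linear(X: int, L, n: int):
    """Linear candidate f = 1 - r, r = (L - X)/(X(n-1)); exact at both ends."""
    r = _excess_ratio(X, L, n)
    out = np.clip(1.0 - r, 0.0, 1.0)
    return float(out) if np.isscalar(L) else out


def f_type1(X: int, L, n: int, q: float, form: str = "power"):
    """Type I candidate, default f = 1 - r^q.

    The printed source formula does not fix where q attaches; the power form
    is the reading whose fitted optimum matches the reported Type I value.
    ``form="slope"`` selects the alternative reading 1 - q*r (clipped to
    [0, 1]), a tunable-slope variant of the linear candidate.
    """
    if q <= 0:
        raise ValueError(f"q must be positive, got {q}")
    r = _excess_ratio(X, L, n)
    if form == "power":
        out = 1.0 - r ** q
    elif form == "slope":
        out = np.clip(1.0 - q * r, 0.0, 1.0)
    else:
        raise ValueError(f"unknown Type I form {form!r}")
    return float(out) if np.isscalar(L) else out


def f_type2(X: int, L, n: int, q: float):
    """Type II candidate f = (1 - r)^q — the working probability function.

    Monotonically decreasing in L for fixed (X, n, q); exactly 1 at L = X and
    0 at L = nX for every q > 0.
    """
    if q <= 0:
        raise ValueError(f"q must be positive, got {q}")
    r = _excess_ratio(X, L, n)
    out = (1.0 - r) ** q
    return float(out) if np.isscalar(L) else out


def calibrated_q(n: int) -> float:
    """Calibrated Type II exponent q(n) = 0.3146 n + 1.3615."""
    return Q_VS_N_SLOPE * n + Q_VS_N_INTERCEPT


def f_calibrated(X: int, L, n: int):
    """Type II with the stochastic-route calibrated exponent q(n)."""
    return f_type2(X, L, n, calibrated_q(n))


# ---------------------------------------------------------------------------
# Probability table container
# ---------------------------------------------------------------------------

@dataclass
class ProbabilityTable:
    """Estimated or exact f(X, L, n) over the full L grid [X, nX].

    ``values`` maps each integer L to f-hat in [0, 1]; the entries at L = X
    and L = nX are exactly 1 and 0.  ``seed`` is -1 when none was supplied.
    """

    n: int
    X: int
    values: dict[int, float]
    reps: int
    seed: int
    method: str = "monte_carlo"

    def __post_init__(self) -> None:
        for L, v in self.values.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"f({L}) = {v} outside [0, 1]")
        if self.X in self.values and self.values[self.X] != 1.0:
            raise ValueError("value at L = X must be exactly 1")
        nX = self.n * self.X
        if nX in self.values and self.n > 1 and self.values[nX] != 0.0:
            raise ValueError("value at L = nX must be exactly 0")

    @property
    def L_grid(self) -> np.ndarray:
        return np.array(sorted(self.values), dtype=int)

    def f_array(self, L_grid: np.ndarray | None = None) -> np.ndarray:
        grid = self.L_grid if L_grid is None else np.asarray(L_grid)
        missing = [int(l) for l in grid if int(l) not in self.values]
        if missing:
            raise KeyError(f"table missing L values: {missing}")
        return np.array([self.values[int(l)] for l in grid])

    def is_complete(self) -> bool:
        return all(l in self.values for l in range(self.X, self.n * self.X + 1))

    def to_frame(self) -> pd.DataFrame:
        grid = self.L_grid
        return pd.DataFrame(
            {
                "n": self.n,
                "X": self.X,
                "L": grid,
                "f": self.f_array(grid),
                "method": self.method,
                "reps": self.reps,
                "seed": self.seed,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        # %.17g keeps the round trip bit-exact
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ProbabilityTable":
        df = pd.read_csv(path, float_precision="round_trip")
        for col in ("n", "X", "method", "reps", "seed"):
            if df[col].nunique() != 1:
                raise ValueError(f"column {col!r} must be constant in a table file")
        return cls(
            n=int(df["n"].iloc[0]),
            X=int(df["X"].iloc[0]),
            values={int(l): float(f) for l, f in zip(df["L"], df["f"])},
            reps=int(df["reps"].iloc[0]),
            seed=int(df["seed"].iloc[0]),
            method=str(df["method"].iloc[0]),
        )
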