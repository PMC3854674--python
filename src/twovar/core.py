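"""Domain types for multi-step reaction chains and their two-variable reduction.

A linear chain  B1 -> B2 -> ... -> Bn -> P  of irreversible first-order
conversions is summarised by two lumped variables: the total molecule count

    X = sum_i [Bi]

and the total *length*

    L = sum_i (n - i + 1) [Bi],

where the length of a molecule in state Bi is the number of reaction steps it
still has to take before reaching the product P (so B1 has length n, Bn has
length 1).  The product P never enters X or L.  For any valid state either
X = L = 0 or X <= L <= n*X.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import yaml

__all__ = [
    "ChainSpec",
    "DetailedState",
    "TwoVarState",
    "total_number",
    "total_length",
    "project",
    "harmonic_mean_rate",
]


@dataclass(frozen=True)
class ChainSpec:
    """An n-step linear chain B1 -> ... -> Bn -> P with per-step rate constants.

    Parameters
    ----------
    n : number of reaction steps (>= 1).
    rates : the n positive rate constants k1..kn, in events per unit time.
    product_absorbing : whether the product P accumulates (True) or is void.
    """

    n: int
    rates: tuple[float, ...]
    product_absorbing: bool = True

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        object.__setattr__(self, "rates", tuple(float(r) for r in self.rates))
        if len(self.rates) != self.n:
            raise ValueError(
                f"expected {self.n} rates, got {len(self.rates)}"
            )
        if any(r <= 0 for r in self.rates):
            raise ValueError("all rate constants must be positive")

    @classmethod
    def equal_rates(cls, n: int, k: float, product_absorbing: bool = True) -> "ChainSpec":
        return cls(n=n, rates=(float(k),) * n, product_absorbing=product_absorbing)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "rates": list(self.rates),
            "product_absorbing": self.product_absorbing,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChainSpec":
        return cls(
            n=int(d["n"]),
            rates=tuple(d["rates"]),
            product_absorbing=bool(d.get("product_absorbing", True)),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "ChainSpec":
        return cls.from_dict(json.loads(s))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict())

    @classmethod
    def from_yaml(cls, s: str) -> "ChainSpec":
        return cls.from_dict(yaml.safe_load(s))


@dataclass(frozen=True)
class DetailedState:
    """Per-species state of a chain: counts of B1..Bn plus the product count."""

    counts: tuple[int, ...]
    product: int = 0
    time: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))
        if any(c < 0 for c in self.counts):
            raise ValueError("species counts must be non-negative")
        if self.product < 0:
            raise ValueError("product count must be non-negative")
        if self.time < 0:
            raise ValueError("time must be non-negative")

    @property
    def n(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class TwoVarState:
    """Lumped state: total molecule number X and total length L."""

    X: int
    L: int
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.X < 0 or self.L < 0:
            raise ValueError("X and L must be non-negative")
        if self.X == 0 and self.L != 0:
            raise ValueError("L must be 0 when X is 0")
        if self.X > 0 and self.L < self.X:
            raise ValueError(f"L must be >= X, got X={self.X}, L={self.L}")
        if self.time < 0:
            raise ValueError("time must be non-negative")


def total_number(state: DetailedState) -> int:
    """Total molecule count X = sum_i [Bi] (product excluded)."""
    return sum(state.counts)


def total_length(state: DetailedState) -> int:
    """Total length L = sum_i (n - i + 1) [Bi]; Bi has length n - i + 1."""
    n = state.n
    return sum((n - i) * c for i, c in enumerate(state.counts))


def project(state: DetailedState) -> TwoVarState:
    """Project a detailed state onto the lumped (X, L) pair.

    The result satisfies X <= L <= n*X (or X = L = 0) by construction.
    """
    return TwoVarState(X=total_number(state), L=total_length(state), time=state.time)


def harmonic_mean_rate(rates: Sequence[float]) -> float:
    """Harmonic mean m / sum(1/k_j) of m positive rate constants.

    This is the single rate constant assigned to the lumped two-variable
    channel; for equal rates it reduces to the common value.
    """
    rates = [float(r) for r in rates]
    if not rates:
        raise ValueError("rates must be non-empty")
    if any(r <= 0 for r in rates):
        raise ValueError("all rates must be positive")
    return len(rates) / sum(1.0 / r for r in rates)
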