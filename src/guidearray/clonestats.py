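"""Clone-screening probability model for ordered gRNA arrays.

The model composes four probabilities.  p(G) is the chance a single gRNA
unit carries no consequential mutation (1 minus the observed mutated-unit
fraction); a k-unit array is mutation-free with p(A) = p(G)^k, assuming
independence between units (they are synthesized in separate PCA
reactions).  With p(F) the chance an assembly is full length, a picked
clone is usable with p(C) = p(A) * p(F), and screening n independent
colonies recovers at least one usable clone with p(U) = 1 - (1 - p(C))^n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ScreeningModel",
    "p_unit_ok",
    "p_array_ok",
    "p_clone_ok",
    "p_usable",
    "colonies_needed",
]


def _check_prob(name: str, value: float) -> None:
    if not 0 <= value <= 1:
        raise ValueError(f"{name}={value} is not a probability")


def p_unit_ok(mutated_units: int, total_units: int) -> float:
    """p(G): fraction of units with no consequential mutation."""
    if total_units <= 0:
        raise ValueError("total_units must be positive")
    if not 0 <= mutated_units <= total_units:
        raise ValueError("mutated_units must be between 0 and total_units")
    return 1 - mutated_units / total_units


def p_array_ok(p_unit: float, k: int) -> float:
    """p(A) = p(G)^k: a k-unit array with no mutated unit."""
    _check_prob("p_unit", p_unit)
    if k < 1:
        raise ValueError("k must be >= 1")
    return p_unit ** k


def p_clone_ok(p_unit: float, p_full_length: float, k: int) -> float:
    """p(C) = p(G)^k * p(F): a picked clone is full length and clean."""
    _check_prob("p_full_length", p_full_length)
    return p_array_ok(p_unit, k) * p_full_length


def p_usable(p_unit: float, p_full_length: float, k: int, n: int) -> float:
    """p(U) = 1 - (1 - p(C))^n: at least one usable clone in n colonies."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return 1 - (1 - p_clone_ok(p_unit, p_full_length, k)) ** n


def colonies_needed(
    p_unit: float, p_full_length: float, k: int, confidence: float
) -> int:
    """Smallest n with p_usable >= confidence.

    Closed form ceil(log(1-confidence) / log(1-p(C))), with the edge cases
    handled exactly.
    """
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    pc = p_clone_ok(p_unit, p_full_length, k)
    if pc == 0:
        raise ValueError("p_clone_ok is 0; no number of colonies reaches "
                         "the requested confidence")
    if pc == 1:
        return 1
    n = math.ceil(math.log(1 - confidence) / math.log(1 - pc))
    n = max(n, 1)
    # guard against floating-point edge of the ceil
    while p_usable(p_unit, p_full_length, k, n) < confidence:
        n += 1
    while n > 1 and p_usable(p_unit, p_full_length, k, n - 1) >= confidence:
        n -= 1
    return n


@dataclass(frozen=True)
class ScreeningModel:
    """All five screening probabilities for one parameterization."""

    p_unit_ok: float
    p_full_length: float
    k: int
    n: int

    def __post_init__(self):
        _check_prob("p_unit_ok", self.p_unit_ok)
        _check_prob("p_full_length", self.p_full_length)
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n < 0:
            raise ValueError("n must be >= 0")

    @property
    def p_array_ok(self) -> float:
        return p_array_ok(self.p_unit_ok, self.k)

    @property
    def p_clone_ok(self) -> float:
        return p_clone_ok(self.p_unit_ok, self.p_full_length, self.k)

    @property
    def p_usable(self) -> float:
        return p_usable(self.p_unit_ok, self.p_full_length, self.k, self.n)

    def as_dict(self) -> dict[str, float]:
        return dict(
            p_unit_ok=self.p_unit_ok,
            p_full_length=self.p_full_length,
            k=self.k,
            n=self.n,
            p_array_ok=self.p_array_ok,
            p_clone_ok=self.p_clone_ok,
            p_usable=self.p_usable,
        )
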