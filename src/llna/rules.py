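"""Life-like transition rules and their density-interval semantics.

A Life-like rule is written ``B<digits>/S<digits>`` with digits drawn from
0-8: the birth set lists the alive-neighbor counts that turn a dead cell
alive, the survival set those that keep an alive cell alive.  On a network
the neighbor count is replaced by the neighborhood density rho (fraction of
alive neighbors), and each digit ``x`` is identified with the density
interval [x/9, (x+1)/9), the last interval [8/9, 1] being closed.  There
are 2**18 = 262144 distinct rules.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

N_RULES = 2**18

#: Interior interval boundaries 1/9 .. 8/9.  Interval membership is decided
#: by comparing against exactly these floating-point values everywhere, so
#: the nine intervals partition [0, 1] bitwise.
INTERVAL_BOUNDS = np.arange(1, 9) / 9.0

_RULE_RE = re.compile(r"^B([0-8]*)/S([0-8]*)$")


class RuleParseError(ValueError):
    """Raised when a rule string is not valid ``B<digits>/S<digits>`` text."""


def _digit_table(digits: frozenset[int]) -> np.ndarray:
    table = np.zeros(9, dtype=bool)
    if digits:
        table[sorted(digits)] = True
    return table


@dataclass(frozen=True)
class LifeLikeRule:
    """An outer-totalistic two-state rule, e.g. ``B3/S23`` (Game of Life)."""

    birth: frozenset = field(default_factory=frozenset)
    survival: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for name, digits in (("birth", self.birth), ("survival", self.survival)):
            if not all(isinstance(d, (int, np.integer)) and 0 <= d <= 8 for d in digits):
                raise ValueError(f"{name} digits must lie in 0..8, got {sorted(digits)}")
        object.__setattr__(self, "birth", frozenset(int(d) for d in self.birth))
        object.__setattr__(self, "survival", frozenset(int(d) for d in self.survival))

    @property
    def canonical_name(self) -> str:
        b = "".join(str(d) for d in sorted(self.birth))
        s = "".join(str(d) for d in sorted(self.survival))
        return f"B{b}/S{s}"

    @property
    def mask(self) -> int:
        """18-bit encoding: bit i = digit i in B (i<9), digit i-9 in S (i>=9)."""
        m = 0
        for d in self.birth:
            m |= 1 << d
        for d in self.survival:
            m |= 1 << (9 + d)
        return m

    @classmethod
    def from_mask(cls, mask: int) -> "LifeLikeRule":
        if not 0 <= mask < N_RULES:
            raise ValueError(f"rule mask must lie in 0..{N_RULES - 1}, got {mask}")
        birth = frozenset(d for d in range(9) if mask & (1 << d))
        survival = frozenset(d for d in range(9) if mask & (1 << (9 + d)))
        return cls(birth, survival)

    def birth_table(self) -> np.ndarray:
        """Boolean lookup over interval indices 0..8."""
        return _digit_table(self.birth)

    def survival_table(self) -> np.ndarray:
        return _digit_table(self.survival)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical_name


def parse_rule(name: str) -> LifeLikeRule:
    """Parse ``B<digits>/S<digits>`` text (case-insensitive) into a rule.

    Digits must come from 0-8 without repeats; either side may be empty.
    """
    text = name.strip().upper()
    m = _RULE_RE.match(text)
    if m is None:
        raise RuleParseError(
            f"rule text {name!r} does not match B<digits>/S<digits> with digits 0-8"
        )
    sets = []
    for token, side in zip(m.groups(), "BS"):
        digits = [int(c) for c in token]
        if len(set(digits)) != len(digits):
            raise RuleParseError(f"repeated digit in {side}{token!r} of rule {name!r}")
        sets.append(frozenset(digits))
    return LifeLikeRule(birth=sets[0], survival=sets[1])


def enumerate_rules() -> Iterator[LifeLikeRule]:
    """Yield all 262144 Life-like rules, ascending in the 18-bit mask.

    Bit i (i < 9) of the mask marks digit i in the birth set; bit 9 + i
    marks digit i in the survival set.  The first rule is B/S (mask 0).
    """
    for mask in range(N_RULES):
        yield LifeLikeRule.from_mask(mask)


def interval_index(rho) -> np.ndarray | int:
    """Map density rho in [0, 1] to its interval digit x in 0..8.

    Vectorized; uses the shared INTERVAL_BOUNDS comparisons so scalar and
    array paths agree bitwise.
    """
    arr = np.asarray(rho, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("density must lie in [0, 1]")
    idx = np.searchsorted(INTERVAL_BOUNDS, arr, side="right")
    if np.isscalar(rho) or arr.ndim == 0:
        return int(idx)
    return idx


def interval_contains(x: int, rho: float) -> bool:
    """True iff rho falls in digit x's density interval.

    The intervals [x/9, (x+1)/9) for x <= 7 and [8/9, 1] partition [0, 1]:
    exactly one x answers True for any admissible rho.
    """
    if not 0 <= x <= 8:
        raise ValueError(f"digit must lie in 0..8, got {x}")
    return interval_index(rho) == x


def birth_satisfied(rule: LifeLikeRule, rho: float) -> bool:
    """True iff some digit of the birth set covers density rho."""
    return bool(rule.birth_table()[interval_index(rho)])


def survival_satisfied(rule: LifeLikeRule, rho: float) -> bool:
    """True iff some digit of the survival set covers density rho."""
    return bool(rule.survival_table()[interval_index(rho)])
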