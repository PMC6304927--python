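"""Rational Caputo derivative orders.

The multi-order stability theory requires each derivative order to be a
rational number alpha = k/m' in (0, 1]: the transformed eigenvalue problem
is polynomial only after substituting lambda -> lambda^(1/m) with m the
least common multiple of the orders' denominators.  Orders are therefore
stored as exact reduced fractions; decimal input is converted to the
nearest fraction with denominator at most ``MAX_DENOMINATOR``.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import gcd, lcm

__all__ = ["RationalOrder", "MAX_DENOMINATOR", "order_lcm"]

#: Largest denominator accepted when converting a decimal order to a fraction.
MAX_DENOMINATOR = 1000


@dataclass(frozen=True)
class RationalOrder:
    """A derivative order k/m' with 0 < k/m' <= 1, stored reduced."""

    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        num, den = int(self.numerator), int(self.denominator)
        if den <= 0 or num <= 0:
            raise ValueError(
                f"order must be a positive rational, got {num}/{den}"
            )
        g = gcd(num, den)
        num, den = num // g, den // g
        if num > den:
            raise ValueError(f"order must lie in (0, 1], got {num}/{den}")
        object.__setattr__(self, "numerator", num)
        object.__setattr__(self, "denominator", den)

    @classmethod
    def from_value(cls, value) -> "RationalOrder":
        """Coerce a float, Fraction, string ("4/5" or "0.8") or RationalOrder.

        Floats are snapped to the closest fraction with denominator at most
        ``MAX_DENOMINATOR`` (continued-fraction best approximation), so 0.8
        becomes exactly 4/5 rather than the 53-bit binary float.
        """
        if isinstance(value, cls):
            return value
        if isinstance(value, Fraction):
            return cls(value.numerator, value.denominator)
        if isinstance(value, int):
            return cls(value, 1)
        if isinstance(value, str):
            frac = Fraction(value)
            return cls(frac.numerator, frac.denominator)
        if isinstance(value, float):
            frac = Fraction(value).limit_denominator(MAX_DENOMINATOR)
            return cls(frac.numerator, frac.denominator)
        raise TypeError(f"cannot interpret {value!r} as a derivative order")

    @property
    def value(self) -> float:
        return self.numerator / self.denominator

    def as_fraction(self) -> Fraction:
        return Fraction(self.numerator, self.denominator)

    def __float__(self) -> float:
        return self.value

    def __str__(self) -> str:
        return f"{self.numerator}/{self.denominator}"


def order_lcm(*orders: RationalOrder) -> int:
    """Least common multiple of the denominators of the given orders.

    This is the integer m of the sector condition |arg lambda| > pi/(2m).
    """
    return lcm(*(o.denominator for o in orders))
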