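"""Two-population fractional pathogen / memory-T-cell model.

The model couples a logistically growing pathogen (tumour) population P(t)
with the specific adaptive immune response T(t) (memory T cells) through
saturating Holling type-II interactions, under Caputo derivatives of
possibly different rational orders alpha1 and alpha2:

    D^alpha1 P = beta_P * P * (1 - P/Lambda) - (c*P / (1 + a*P)) * T
    D^alpha2 T = (mu*P / (1 + nu*P)) * T - delta * T

All seven rates are strictly positive.  The system always has the
disease-free equilibrium E0 = (0, 0) and the pathogen-only equilibrium
E1 = (Lambda, 0); a coexistence equilibrium E2 = (P*, T*) with

    P* = delta / (mu - nu*delta)
    T* = beta_P * (1 - P*/Lambda) / (c / (1 + a*P*))

is biologically meaningful exactly when mu - nu*delta > 0 and P* < Lambda.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Tuple

from .orders import RationalOrder

__all__ = [
    "ModelParams",
    "State",
    "Equilibrium",
    "rhs",
    "equilibria",
    "viability_check",
]

_RATE_FIELDS = ("beta_P", "Lambda", "c", "a", "mu", "nu", "delta")


@dataclass(frozen=True)
class ModelParams:
    """Rates and derivative orders of the pathogen-immune system.

    Parameters
    ----------
    beta_P : float
        Pathogen (tumour) growth rate, day^-1.
    Lambda : float
        Pathogen carrying capacity, cells.
    c : float
        Maximum rate at which immune cells kill the pathogen, day^-1.
    a : float
        Immune-cell level producing the half-maximum killing effect.
    mu : float
        Maximum proliferation rate of memory T cells, day^-1.
    nu : float
        Pathogen size at which T-cell growth is half its maximum.
    delta : float
        Natural death rate of memory T cells, day^-1.
    alpha1, alpha2 : RationalOrder or float
        Caputo derivative orders of the P- and T-equation, rationals
        in (0, 1].  Floats are snapped to exact fractions.
    """

    beta_P: float
    Lambda: float
    c: float
    a: float
    mu: float
    nu: float
    delta: float
    alpha1: RationalOrder = field(default=RationalOrder(1, 1))
    alpha2: RationalOrder = field(default=RationalOrder(1, 1))

    def __post_init__(self) -> None:
        bad = [
            name
            for name in _RATE_FIELDS
            if not (
                math.isfinite(getattr(self, name)) and getattr(self, name) > 0
            )
        ]
        if bad:
            raise ValueError(
                "all rates must be finite and strictly positive; offending "
                "field(s): " + ", ".join(bad)
            )
        object.__setattr__(self, "alpha1", RationalOrder.from_value(self.alpha1))
        object.__setattr__(self, "alpha2", RationalOrder.from_value(self.alpha2))

    @property
    def immune_viable(self) -> bool:
        """True when the saturated T-cell growth rate mu/nu exceeds delta.

        At very high pathogen load the per-capita T-cell growth rate tends
        to mu/nu; replication must then outpace death for the immune
        response to be sustainable.  Equality counts as a violation.
        """
        return self.mu / self.nu > self.delta

    @property
    def viability_margin(self) -> float:
        return self.mu / self.nu - self.delta


@dataclass(frozen=True)
class State:
    """A point (P, T) in population space; both components in cells."""

    P: float
    T: float

    def __iter__(self):
        yield self.P
        yield self.T


@dataclass(frozen=True)
class Equilibrium:
    """A labelled steady state with its biological-existence verdict."""

    label: str  # "E0", "E1" or "E2"
    P: float
    T: float
    exists_biologically: bool
    condition_trace: str

    def as_state(self) -> State:
        return State(self.P, self.T)


def rhs(params: ModelParams, state: State) -> Tuple[float, float]:
    """Right-hand side (f, g) of the fractional system at ``state``.

    Returns the pair that the Caputo derivatives of P and T equal; it is
    the classical vector field of the same rate equations, so it also
    drives the integer-order (alpha = 1) limit.
    """
    P, T = state.P, state.T
    if not (math.isfinite(P) and math.isfinite(T)):
        raise ValueError(f"state must be finite, got ({P}, {T})")
    p = params
    f = p.beta_P * P * (1.0 - P / p.Lambda) - (p.c * P / (1.0 + p.a * P)) * T
    g = (p.mu * P / (1.0 + p.nu * P)) * T - p.delta * T
    return f, g


def viability_check(params: ModelParams) -> Tuple[bool, float]:
    """Whether saturated immune replication beats death, with its margin.

    Returns ``(mu/nu > delta, mu/nu - delta)``; the boundary
    ``mu/nu == delta`` is reported as a violation (margin 0).
    """
    return params.immune_viable, params.viability_margin


def equilibria(params: ModelParams) -> List[Equilibrium]:
    """All three equilibrium records E0, E1, E2 (always length 3).

    E0 and E1 always exist.  The interior point E2 is computed in closed
    form; when the denominator mu - nu*delta is nonpositive, or when
    P* >= Lambda (so T* <= 0), E2 is flagged biologically nonexistent.
    Degenerate cases are recorded in the condition trace, never raised.
    """
    p = params
    out = [
        Equilibrium("E0", 0.0, 0.0, True, "disease-free point; always exists"),
        Equilibrium(
            "E1",
            p.Lambda,
            0.0,
            True,
            f"pathogen-only point (Lambda, 0) = ({p.Lambda:g}, 0); always exists",
        ),
    ]
    denom = p.mu - p.nu * p.delta
    if denom == 0.0:
        out.append(
            Equilibrium(
                "E2",
                math.nan,
                math.nan,
                False,
                "degenerate denominator: mu - nu*delta = 0, so "
                "P* = delta/(mu - nu*delta) is undefined",
            )
        )
        return out

    P_star = p.delta / denom
    T_star = p.beta_P * (1.0 - P_star / p.Lambda) / (p.c / (1.0 + p.a * P_star))
    if denom < 0.0:
        exists = False
        trace = (
            f"mu - nu*delta = {denom:g} < 0: formal P* = {P_star:g} is "
            "negative, E2 does not exist biologically"
        )
    elif P_star == p.Lambda:
        exists = False
        trace = (
            f"boundary case P* = delta/(mu - nu*delta) = {P_star:g} = Lambda: "
            "T* = 0 and E2 coincides with E1; flagged nonexistent"
        )
    else:
        exists = P_star < p.Lambda
        rel = "<" if exists else ">"
        verdict = "exists" if exists else "is biologically meaningless"
        trace = (
            f"delta/(mu - nu*delta) = {P_star:g} {rel} Lambda = {p.Lambda:g}: "
            f"E2 {verdict}"
        )
    out.append(Equilibrium("E2", P_star, T_star, exists, trace))
    return out
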