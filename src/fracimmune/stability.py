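"""Local stability of equilibria under multi-order Caputo dynamics.

For a two-component system with rational orders alpha1 = k1/m1 and
alpha2 = k2/m2 the eigenvalue problem at an equilibrium is

    det(diag(lambda^(m*alpha1), lambda^(m*alpha2)) - J) = 0,

with J the Jacobian at the equilibrium and m = lcm(m1, m2).  The exponents
m*alpha1 and m*alpha2 are integers, so the left side expands to a genuine
polynomial of degree m*(alpha1 + alpha2).  The equilibrium is locally
asymptotically stable (LAS) when every root satisfies the sector condition

    |arg(lambda)| > pi / (2 m).

The disease-free point E0 and the pathogen-only point E1 admit closed-form
verdicts (E0 is always unstable; E1 is LAS exactly when the T-cell growth
rate at carrying capacity, mu*Lambda/(1 + nu*Lambda), stays below the death
rate delta).  The interior point E2 is classified by solving its sparse
characteristic polynomial

    lambda^(m(a1+a2)) - beta_P*(A1*(A2+1) - 1)*lambda^(m*a2)
        + beta_P*delta^2*A1 / (mu*Lambda*(1 - A1)) = 0,

where A1 = 1 - P*/Lambda and A2 = a*P*/(a*P* + 1).
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .model import Equilibrium, ModelParams, State, equilibria, rhs
from .orders import RationalOrder, order_lcm

__all__ = [
    "CharPoly",
    "StabilityReport",
    "AngleResidual",
    "jacobian",
    "sector_order_m",
    "characteristic_polynomial",
    "classify",
    "classify_equal_order",
    "angle_equation_check",
]

#: |min |arg| - threshold| below this (degrees) is reported as marginal.
MARGINAL_TOL_DEG = 1e-8

#: roots with |Im| < snap_tol * max(1, |Re|) are snapped onto the real axis
#: before arguments are taken (arg is discontinuous there).
IMAG_SNAP_TOL = 1e-10


def jacobian(params: ModelParams, point: State) -> np.ndarray:
    """Analytic 2x2 Jacobian of the rate field (f, g) at ``point``."""
    P, T = point.P, point.T
    p = params
    df_dP = p.beta_P * (1.0 - 2.0 * P / p.Lambda) - p.c * T / (1.0 + p.a * P) ** 2
    df_dT = -p.c * P / (1.0 + p.a * P)
    dg_dP = p.mu * T / (1.0 + p.nu * P) ** 2
    dg_dT = p.mu * P / (1.0 + p.nu * P) - p.delta
    return np.array([[df_dP, df_dT], [dg_dP, dg_dT]])


def sector_order_m(alpha1: RationalOrder, alpha2: RationalOrder) -> int:
    """The integer m of the sector condition: lcm of the orders' denominators."""
    return order_lcm(
        RationalOrder.from_value(alpha1), RationalOrder.from_value(alpha2)
    )


@dataclass(frozen=True)
class CharPoly:
    """Sparse characteristic polynomial in the transformed variable.

    ``coefficients`` maps integer exponent -> real coefficient; only the
    nonzero entries (plus the leading one) are stored.  For the interior
    equilibrium the nonzero exponents are m(a1+a2), m*a2 and 0.  ``A1`` and
    ``A2`` are the dimensionless combinations 1 - P*/Lambda and
    a*P*/(a*P*+1); they are only set for E2.
    """

    degree: int
    coefficients: Dict[int, float]
    m: int
    A1: Optional[float] = None
    A2: Optional[float] = None

    def dense(self) -> np.ndarray:
        """Coefficient vector, highest power first (numpy convention)."""
        c = np.zeros(self.degree + 1)
        for exp, coef in self.coefficients.items():
            c[self.degree - exp] = coef
        return c

    def __call__(self, lam: complex) -> complex:
        return sum(coef * lam**exp for exp, coef in self.coefficients.items())

    def roots(self) -> np.ndarray:
        """All ``degree`` roots, via the companion matrix of the dense form.

        Near-real roots (|Im| < 1e-10 relative) are snapped to the axis so
        that their arguments come out exactly 0 or pi.
        """
        r = np.roots(self.dense())
        snap = np.abs(r.imag) < IMAG_SNAP_TOL * np.maximum(1.0, np.abs(r.real))
        r[snap] = r[snap].real
        return r

    def format(self, decimals: int = 4) -> str:
        parts = []
        for exp in sorted(self.coefficients, reverse=True):
            coef = self.coefficients[exp]
            mag = f"{abs(coef):.{decimals}f}"
            power = "" if exp == 0 else ("λ" if exp == 1 else f"λ^{exp}")
            if exp == self.degree and abs(coef) == 1.0 and power:
                term = power
            else:
                term = mag + ("*" + power if power else "")
            if not parts:
                parts.append(("-" if coef < 0 else "") + term)
            else:
                parts.append(("- " if coef < 0 else "+ ") + term)
        return " ".join(parts) + " = 0"


@dataclass(frozen=True)
class StabilityReport:
    """Classification record for one equilibrium.

    ``threshold_deg`` is the sector half-angle in degrees: 90/m for the
    multi-order methods, alpha*90 for the equal-order method (which works
    in the untransformed eigenvalue plane of the 2x2 Jacobian).
    ``verdict`` is one of ``LAS``, ``unstable``, ``marginal`` or
    ``not_applicable`` (E2 requested while biologically nonexistent).
    """

    equilibrium: Equilibrium
    m: int
    char_poly: Optional[CharPoly]
    roots: Tuple[complex, ...]
    args_deg: Tuple[float, ...]
    threshold_deg: float
    min_abs_arg_deg: float
    verdict: str
    method: str
    details: Dict[str, object] = field(default_factory=dict)


def characteristic_polynomial(params: ModelParams, eq: Equilibrium) -> CharPoly:
    """Characteristic polynomial of the transformed eigenvalue problem at ``eq``.

    Expanding det(diag(lam^(m a1), lam^(m a2)) - J) gives the sparse
    polynomial

        lam^(m(a1+a2)) - J22*lam^(m a1) - J11*lam^(m a2) + det(J).

    Requesting E2 while it is biologically nonexistent is a precondition
    violation and raises ``ValueError``.
    """
    if eq.label == "E2" and not eq.exists_biologically:
        raise ValueError(
            "characteristic polynomial at E2 requires biological existence; "
            + eq.condition_trace
        )
    m = sector_order_m(params.alpha1, params.alpha2)
    # integer exponents m*alpha1 and m*alpha2
    e1 = (m // params.alpha1.denominator) * params.alpha1.numerator
    e2 = (m // params.alpha2.denominator) * params.alpha2.numerator
    J = jacobian(params, eq.as_state())
    degree = e1 + e2
    coeffs: Dict[int, float] = {degree: 1.0}
    for exp, coef in ((e1, -J[1, 1]), (e2, -J[0, 0])):
        if coef != 0.0:
            coeffs[exp] = coeffs.get(exp, 0.0) + coef
    coeffs[0] = coeffs.get(0, 0.0) + float(np.linalg.det(J))
    coeffs = {e: c for e, c in coeffs.items() if c != 0.0 or e == degree}

    A1 = A2 = None
    if eq.label == "E2":
        A1 = 1.0 - eq.P / params.Lambda
        A2 = params.a * eq.P / (params.a * eq.P + 1.0)
    return CharPoly(degree=degree, coefficients=coeffs, m=m, A1=A1, A2=A2)


def _sector_verdict(args_deg, threshold_deg: float) -> Tuple[str, float]:
    min_abs = min(abs(a) for a in args_deg)
    if abs(min_abs - threshold_deg) < MARGINAL_TOL_DEG:
        return "marginal", min_abs
    return ("LAS" if min_abs > threshold_deg else "unstable"), min_abs


def _args_deg(roots: np.ndarray) -> Tuple[float, ...]:
    """Principal arguments in degrees, convention (-180, 180]."""
    out = []
    for r in roots:
        a = math.degrees(cmath.phase(r))  # phase in (-pi, pi]
        if a == -180.0:
            a = 180.0
        out.append(a)
    return tuple(out)


def classify(
    params: ModelParams, eq: Equilibrium, force_roots: bool = False
) -> StabilityReport:
    """Stability verdict for one equilibrium record.

    E0 and E1 are settled analytically (their transformed eigenvalue
    problems factor into lam^(m a_i) = const, whose root arguments are
    known exactly); the root-finding sector test is used for E2, or for
    any equilibrium when ``force_roots`` is set.  A biologically
    nonexistent E2 yields verdict ``not_applicable``.
    """
    m = sector_order_m(params.alpha1, params.alpha2)
    threshold = 90.0 / m

    if eq.label == "E2" and not eq.exists_biologically:
        return StabilityReport(
            equilibrium=eq, m=m, char_poly=None, roots=(), args_deg=(),
            threshold_deg=threshold, min_abs_arg_deg=math.nan,
            verdict="not_applicable", method="sector_multiorder",
            details={"reason": eq.condition_trace},
        )

    poly = characteristic_polynomial(params, eq)
    roots = poly.roots()
    args = _args_deg(roots)

    if eq.label == "E0" and not force_roots:
        # lam^(m a1) = beta_P > 0 has a root on the positive real axis
        # (arg 0 < pi/2m), so E0 can never satisfy the sector condition.
        return StabilityReport(
            equilibrium=eq, m=m, char_poly=poly, roots=tuple(roots),
            args_deg=args, threshold_deg=threshold, min_abs_arg_deg=0.0,
            verdict="unstable", method="analytic_E0",
            details={"positive_real_root": params.beta_P ** (1.0 / (
                m * params.alpha1.value))},
        )

    if eq.label == "E1" and not force_roots:
        # lam^(m a1) = -beta_P always yields |arg| = pi/(m a1) > pi/2m;
        # the verdict hinges on lam^(m a2) = mu*Lambda/(1+nu*Lambda) - delta.
        growth = params.mu * params.Lambda / (1.0 + params.nu * params.Lambda)
        las = growth < params.delta
        min_arg = (
            min(180.0 / (m * params.alpha1.value),
                180.0 / (m * params.alpha2.value))
            if las
            else 0.0
        )
        details = {
            "growth_at_capacity": growth,
            "delta": params.delta,
            "condition": f"mu*Lambda/(1+nu*Lambda) = {growth:g} "
                         f"{'<' if las else '>='} delta = {params.delta:g}",
        }
        denom = params.mu - params.nu * params.delta
        if denom > 0:
            details["threshold_quantity"] = params.delta / denom
            details["condition"] = (
                f"delta/(mu - nu*delta) = {params.delta / denom:g} "
                f"{'>' if las else '<='} Lambda = {params.Lambda:g}"
            )
        return StabilityReport(
            equilibrium=eq, m=m, char_poly=poly, roots=tuple(roots),
            args_deg=args, threshold_deg=threshold, min_abs_arg_deg=min_arg,
            verdict="LAS" if las else "unstable", method="analytic_E1",
            details=details,
        )

    verdict, min_abs = _sector_verdict(args, threshold)
    return StabilityReport(
        equilibrium=eq, m=m, char_poly=poly, roots=tuple(roots),
        args_deg=args, threshold_deg=threshold, min_abs_arg_deg=min_abs,
        verdict=verdict, method="sector_multiorder",
    )


def classify_equal_order(params: ModelParams) -> StabilityReport:
    """Classify E2 in the commensurate case alpha1 = alpha2 = alpha.

    Works directly with the two eigenvalues of the 2x2 Jacobian: E2 is LAS
    when both satisfy |arg(z)| > alpha*pi/2.  This is equivalent to the
    sector condition on the transformed polynomial but avoids root-finding
    on a large-degree polynomial.  The report's ``details`` carry the two
    closed-form criteria: the Routh-Hurwitz branch (trace < 0, i.e.
    A1*(A2+1) - 1 < 0, gives LAS for every order) and the half-angle
    arccos criterion when its argument lies in [-1, 1].
    """
    if params.alpha1 != params.alpha2:
        raise ValueError(
            "equal-order classification requires alpha1 == alpha2, got "
            f"{params.alpha1} and {params.alpha2}"
        )
    alpha = params.alpha1
    m = alpha.denominator
    eq = equilibria(params)[2]
    threshold = 90.0 * alpha.value
    if not eq.exists_biologically:
        return StabilityReport(
            equilibrium=eq, m=m, char_poly=None, roots=(), args_deg=(),
            threshold_deg=threshold, min_abs_arg_deg=math.nan,
            verdict="not_applicable", method="equal_order",
            details={"reason": eq.condition_trace},
        )

    J = jacobian(params, eq.as_state())
    # quadratic z^2 + a1*z + a2 from det(J - z I) = 0
    a1 = -float(np.trace(J))
    a2 = float(np.linalg.det(J))
    z = np.roots([1.0, a1, a2])
    snap = np.abs(z.imag) < IMAG_SNAP_TOL * np.maximum(1.0, np.abs(z.real))
    z[snap] = z[snap].real
    args = _args_deg(z)
    verdict, min_abs = _sector_verdict(args, threshold)

    A1 = 1.0 - eq.P / params.Lambda
    A2 = params.a * eq.P / (params.a * eq.P + 1.0)
    poly = CharPoly(degree=2, coefficients={2: 1.0, 1: a1, 0: a2}, m=m,
                    A1=A1, A2=A2)

    details: Dict[str, object] = {
        "trace_term": A1 * (A2 + 1.0) - 1.0,
        "routh_hurwitz_LAS": a1 > 0.0 and a2 > 0.0,
    }
    # half-angle criterion: arccos(beta_P*k^2/(2 d) - 1) > pi*alpha, with
    # k = A1(A2+1)-1 and d = delta^2 A1 / (mu Lambda (1-A1)); its argument
    # equals cos(2*arg z) for the complex pair, so it restates the sector
    # test whenever it is defined.
    d = params.delta**2 * A1 / (params.mu * params.Lambda * (1.0 - A1))
    x = params.beta_P * (A1 * (A2 + 1.0) - 1.0) ** 2 / (2.0 * d) - 1.0
    if -1.0 <= x <= 1.0:
        details["half_angle_deg"] = math.degrees(math.acos(x))
        details["half_angle_LAS"] = math.acos(x) > math.pi * alpha.value
    else:
        details["half_angle_LAS"] = "criterion inapplicable"
        details["half_angle_argument"] = x

    return StabilityReport(
        equilibrium=eq, m=m, char_poly=poly, roots=tuple(z), args_deg=args,
        threshold_deg=threshold, min_abs_arg_deg=min_abs, verdict=verdict,
        method="equal_order", details=details,
    )


@dataclass(frozen=True)
class AngleResidual:
    """Residual of the trigonometric angle equation at one root argument."""

    theta_deg: float
    residual: float
    skipped: bool
    reason: str = ""


def angle_equation_check(
    params: ModelParams, thetas_deg: Optional[List[float]] = None
) -> List[AngleResidual]:
    """Residuals of the polar-form angle equation at the E2 root arguments.

    Writing a root as lambda = r*cis(theta) and eliminating r from the real
    and imaginary parts of the characteristic equation leaves a relation in
    theta alone:

        sin(m a2 th)^(a2/a1) * sin(m a1 th) / sin(m(a1+a2) th)^(1+a2/a1)
            = C0 / B^(1+a2/a1),

    with B = beta_P*(A1(A2+1)-1) the magnitude of the middle coefficient
    and C0 the constant term.  Every genuine root argument must satisfy it.
    The fractional powers are evaluated through the positive ratio
    sin(m a2 th)/sin(m(a1+a2) th) (which equals r^(m a1)/B at a root);
    angles where that ratio is nonpositive, where the equation is singular
    (sin(m(a1+a2) th) = 0), or real roots at theta = 180 deg, are skipped
    and flagged.

    By default the angles tested are the computed root arguments of E2;
    arbitrary angles (degrees) can be supplied to probe non-roots.
    """
    eq = equilibria(params)[2]
    if not eq.exists_biologically:
        raise ValueError("angle equation requires a biologically existing E2")
    poly = characteristic_polynomial(params, eq)
    m = poly.m
    ma1 = (m // params.alpha1.denominator) * params.alpha1.numerator
    ma2 = (m // params.alpha2.denominator) * params.alpha2.numerator
    q = params.alpha2.value / params.alpha1.value
    B = -poly.coefficients.get(ma2, 0.0)  # beta_P*(A1(A2+1)-1)
    C0 = poly.coefficients[0]

    if thetas_deg is None:
        rep = classify(params, eq)
        thetas_deg = [a for a in rep.args_deg if abs(abs(a) - 180.0) > 1e-9
                      and abs(a) > 1e-9]

    out: List[AngleResidual] = []
    if B <= 0.0:
        return [
            AngleResidual(th, math.nan, True,
                          "middle coefficient nonpositive; real-power form "
                          "undefined")
            for th in thetas_deg
        ]
    rhs_value = C0 / B ** (1.0 + q)
    for th in thetas_deg:
        t = math.radians(th)
        s = math.sin((ma1 + ma2) * t)
        if abs(s) < 1e-9:
            out.append(AngleResidual(th, math.nan, True,
                                     "sin(m(a1+a2)*theta) = 0: singular"))
            continue
        s1 = math.sin(ma1 * t)
        s2 = math.sin(ma2 * t)
        ratio = s2 / s
        if ratio <= 0.0 or abs(s2) < 1e-12:
            out.append(AngleResidual(th, math.nan, True,
                                     "sin ratio nonpositive: no real "
                                     "fractional power"))
            continue
        lhs_value = ratio ** (1.0 + q) * (s1 / s2)
        out.append(AngleResidual(th, lhs_value - rhs_value, False))
    return out
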