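"""Numerical integration of the multi-order Caputo system.

The time stepper is the fractional Adams-Bashforth-Moulton predictor-
corrector (product-rectangle predictor, product-trapezoidal corrector)
applied component-wise, so that the P- and T-equations may carry
different orders alpha1 and alpha2.  For component i with order a the
update from a uniform grid t_k = t0 + k*h is

  predictor:  y_i(t_{n+1}) = y_i(0) + h^a/Gamma(a+1) *
                  sum_{j=0}^{n} [(n+1-j)^a - (n-j)^a] f_i(t_j, y_j)
  corrector:  y_i(t_{n+1}) = y_i(0) + h^a/Gamma(a+2) *
                  [ f_i(t_{n+1}, y^pred) + a_{0} f_i(t_0, y_0)
                    + sum_{j=1}^{n} a_{j} f_i(t_j, y_j) ]

with trapezoidal weights a_0 = n^(a+1) - (n-a)(n+1)^a and
a_j = (n-j+2)^(a+1) - 2(n-j+1)^(a+1) + (n-j)^(a+1).  The full history is
retained by default (quadratic cost; fine for desk-scale horizons); an
opt-in window truncates the memory at the caller's risk.

A scalar one-parameter Mittag-Leffler routine is provided as the analytic
yardstick: E_a(-t^a) solves the relaxation equation D^a y = -y, y(0) = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.special import gamma as _gamma
from scipy.special import gammaln as _gammaln

from .model import Equilibrium, ModelParams, State, rhs

__all__ = [
    "Trajectory",
    "Outcome",
    "fabm_solve",
    "simulate",
    "mittag_leffler",
    "qualitative_outcome",
]


@dataclass
class Trajectory:
    """A simulated path on a uniform time grid (days)."""

    times: np.ndarray
    P: np.ndarray
    T: np.ndarray
    step: float
    orders: Tuple[float, float]
    corrector_iterations: int
    meta: Dict[str, object] = field(default_factory=dict)

    def final_state(self) -> State:
        return State(float(self.P[-1]), float(self.T[-1]))

    def to_csv(self, path) -> None:
        """Write time, P, T columns with a '#'-prefixed metadata header."""
        header_lines = [
            f"# step_days: {self.step!r}",
            f"# orders: {self.orders[0]!r}, {self.orders[1]!r}",
            f"# corrector_iterations: {self.corrector_iterations}",
        ]
        for key, val in self.meta.items():
            header_lines.append(f"# {key}: {val}")
        body = np.column_stack([self.times, self.P, self.T])
        with open(path, "w") as fh:
            fh.write("\n".join(header_lines) + "\n")
            fh.write("time,P,T\n")
            np.savetxt(fh, body, delimiter=",", fmt="%.12g")


def fabm_solve(
    f: Callable[[float, np.ndarray], np.ndarray],
    y0: Sequence[float],
    orders: Sequence[float],
    t_end: float,
    h: float,
    t0: float = 0.0,
    corrector_iterations: int = 1,
    memory_length: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray, Dict[str, object]]:
    """Integrate D^(orders[i]) y_i = f_i(t, y) from classical initial values.

    Returns ``(times, y, meta)`` with ``y`` of shape (n_steps+1, n_dim).
    If the state leaves the finite range the integration aborts; the
    returned arrays are truncated at the last valid index and
    ``meta["aborted_at_index"]`` records where.

    ``memory_length`` (in time units) optionally truncates the convolution
    history to a sliding window — an approximation (short-memory
    principle) that trades accuracy for speed; off by default.
    """
    if h <= 0:
        raise ValueError("step h must be positive")
    if t_end <= t0:
        raise ValueError("t_end must exceed t0")
    if corrector_iterations < 1:
        raise ValueError("need at least one corrector iteration")
    alphas = np.asarray([float(a) for a in orders], dtype=float)
    if np.any(alphas <= 0) or np.any(alphas > 1):
        raise ValueError("orders must lie in (0, 1]")
    y0 = np.asarray(y0, dtype=float)
    ndim = y0.size
    if alphas.size != ndim:
        raise ValueError("need one order per state component")

    n_steps = int(round((t_end - t0) / h))
    times = t0 + h * np.arange(n_steps + 1)
    k = np.arange(n_steps + 2, dtype=float)
    # per-component power tables: k^a and k^(a+1)
    pow_a = [k**a for a in alphas]
    pow_a1 = [k ** (a + 1.0) for a in alphas]
    c_pred = [h**a / _gamma(a + 1.0) for a in alphas]
    c_corr = [h**a / _gamma(a + 2.0) for a in alphas]

    window = n_steps + 1 if memory_length is None else max(
        2, int(round(memory_length / h))
    )

    y = np.empty((n_steps + 1, ndim))
    fh = np.empty((n_steps + 1, ndim))
    y[0] = y0
    fh[0] = np.asarray(f(times[0], y0), dtype=float)
    meta: Dict[str, object] = {"n_steps": n_steps, "memory_window": window
                               if memory_length is not None else "full"}

    for n in range(n_steps):
        j_lo = max(0, n + 1 - window)
        hist = fh[j_lo : n + 1]  # f at t_{j_lo}..t_n
        nj = n + 1 - j_lo  # number of history points
        y_pred = np.empty(ndim)
        for i in range(ndim):
            pa = pow_a[i]
            # b_j = (n+1-j)^a - (n-j)^a for j = j_lo..n
            b = (pa[1 : nj + 1] - pa[:nj])[::-1]
            y_pred[i] = y0[i] + c_pred[i] * (b @ hist[:, i])
        if not np.all(np.isfinite(y_pred)):
            meta["aborted_at_index"] = n
            return times[: n + 1], y[: n + 1], meta
        f_new = np.asarray(f(times[n + 1], y_pred), dtype=float)

        y_next = np.empty(ndim)
        for _ in range(corrector_iterations):
            for i in range(ndim):
                pa, pa1 = pow_a[i], pow_a1[i]
                a0 = pa1[n] - (n - alphas[i]) * pa[n + 1]
                # a_j for j = 1..n: (n-j+2)^(a+1) - 2(n-j+1)^(a+1) + (n-j)^(a+1)
                acc = a0 * fh[0, i] if j_lo == 0 else 0.0
                if n >= 1:
                    jj = max(1, j_lo)
                    kk = n - jj  # runs kk..0 as j runs jj..n
                    aw = (pa1[2 : kk + 3] - 2.0 * pa1[1 : kk + 2]
                          + pa1[: kk + 1])[::-1]
                    acc = acc + aw @ fh[jj : n + 1, i]
                y_next[i] = y0[i] + c_corr[i] * (acc + f_new[i])
            if not np.all(np.isfinite(y_next)):
                meta["aborted_at_index"] = n
                return times[: n + 1], y[: n + 1], meta
            f_new = np.asarray(f(times[n + 1], y_next), dtype=float)
        y[n + 1] = y_next
        fh[n + 1] = f_new

    return times, y, meta


def simulate(
    params: ModelParams,
    y0: State,
    t_end: float,
    h: float = 0.01,
    corrector_iterations: int = 1,
    memory_length: Optional[float] = None,
) -> Trajectory:
    """Simulate the pathogen / T-cell system from ``y0`` over [0, t_end].

    Orders alpha1 and alpha2 are taken from ``params``; default step is
    0.01 days with one corrector pass.  Undershoots below zero are fed
    back as computed (never clipped — clipping would silently change the
    dynamics); the worst excursion is recorded in ``meta["min_P"]`` /
    ``meta["min_T"]``.
    """
    if y0.P < 0 or y0.T < 0:
        raise ValueError("initial populations must be nonnegative")

    def f(t: float, y: np.ndarray) -> np.ndarray:
        return np.asarray(rhs(params, State(y[0], y[1])))

    times, y, meta = fabm_solve(
        f,
        [y0.P, y0.T],
        [params.alpha1.value, params.alpha2.value],
        t_end,
        h,
        corrector_iterations=corrector_iterations,
        memory_length=memory_length,
    )
    meta["min_P"] = float(y[:, 0].min())
    meta["min_T"] = float(y[:, 1].min())
    return Trajectory(
        times=times,
        P=y[:, 0],
        T=y[:, 1],
        step=h,
        orders=(params.alpha1.value, params.alpha2.value),
        corrector_iterations=corrector_iterations,
        meta=meta,
    )


def mittag_leffler(alpha: float, z: float) -> float:
    """One-parameter Mittag-Leffler function E_alpha(z) for real z.

    Sums the power series sum_k z^k / Gamma(alpha*k + 1) in log space;
    when alternating-series cancellation would cost more than ~4 digits
    of the result, the sum is redone in arbitrary precision (mpmath) with
    enough guard digits.  Accurate to better than 1e-10 over the moderate
    |z| range used as a solver oracle.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if z == 0.0:
        return 1.0
    if alpha == 1.0:
        return math.exp(z)

    log_az = math.log(abs(z))
    total = 1.0
    max_term = 1.0
    k = 1
    while True:
        log_term = k * log_az - _gammaln(alpha * k + 1.0)
        sign = 1.0 if (z > 0 or k % 2 == 0) else -1.0
        term = sign * math.exp(log_term)
        total += term
        max_term = max(max_term, abs(term))
        # safe to stop once terms decay and are negligible
        if abs(term) < 1e-17 * max(1.0, abs(total)) and alpha * k > abs(z) ** (
            1.0 / alpha
        ):
            break
        k += 1
        if k > 10_000:
            raise ArithmeticError("Mittag-Leffler series did not converge")

    if max_term > 1e4 * max(abs(total), 1e-300):
        # heavy cancellation: redo with guard digits
        import mpmath as mp

        extra = int(math.log10(max_term / max(abs(total), 1e-300))) + 1
        with mp.workdps(25 + extra):
            s = mp.nsum(lambda kk: mp.mpf(z) ** kk / mp.gamma(alpha * kk + 1),
                        [0, mp.inf])
            total = float(s)
    return total


@dataclass(frozen=True)
class Outcome:
    """Qualitative long-run classification of a trajectory."""

    kind: str  # "converged_to", "oscillatory", "diverged", "undecided"
    label: Optional[str] = None  # equilibrium label when kind == converged_to

    def __str__(self) -> str:
        return f"converged_to({self.label})" if self.kind == "converged_to" \
            else self.kind


def qualitative_outcome(
    traj: Trajectory,
    eqs: Sequence[Equilibrium],
    window: float = 50.0,
    rel_radius: float = 1e-2,
    osc_frac: float = 0.05,
) -> Outcome:
    """Classify the tail behaviour of a trajectory.

    ``converged_to(label)``: over the trailing ``window`` days the state
    stays within a ball of radius ``rel_radius * (1 + |eq|_inf)`` around a
    single biologically existing equilibrium.  ``oscillatory``: the
    trailing peak-to-trough amplitude of P exceeds ``osc_frac`` of its
    trailing mean without convergence.  ``diverged``: non-finite values or
    unbounded growth.  Otherwise ``undecided``.
    """
    span = traj.times[-1] - traj.times[0]
    if span < 2.0 * window:
        raise ValueError("trajectory must cover at least twice the window")
    if "aborted_at_index" in traj.meta or not (
        np.all(np.isfinite(traj.P)) and np.all(np.isfinite(traj.T))
    ):
        return Outcome("diverged")
    if max(np.abs(traj.P).max(), np.abs(traj.T).max()) > 1e8:
        return Outcome("diverged")

    tail = traj.times >= traj.times[-1] - window
    Pt, Tt = traj.P[tail], traj.T[tail]

    best = None
    for eq in eqs:
        if not eq.exists_biologically:
            continue
        radius = rel_radius * (1.0 + max(abs(eq.P), abs(eq.T)))
        dist = np.maximum(np.abs(Pt - eq.P), np.abs(Tt - eq.T))
        if dist.max() <= radius and (best is None or dist.max() < best[1]):
            best = (eq.label, dist.max())
    if best is not None:
        return Outcome("converged_to", best[0])

    mean_P = float(np.mean(np.abs(Pt)))
    amp = float(Pt.max() - Pt.min())
    if mean_P > 0 and amp > osc_frac * mean_P:
        return Outcome("oscillatory")
    return Outcome("undecided")
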