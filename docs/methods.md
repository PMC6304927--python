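# Methods

## Model and assumptions

The package implements a two-compartment within-host model: pathogen load
`P(t)` (logistic growth, capacity `Λ`, rate `β_P`) interacting with
memory T cells `T(t)` through two saturating Holling type-II terms — a
killing term `cP/(1+aP)·T` and a proliferation term `μP/(1+νP)·T` — with
linear T-cell death `δT`. Both equations carry Caputo fractional
derivatives of rational order in `(0, 1]`, possibly different per
equation ("multi-order" / incommensurate system). The Caputo form is used
so that initial conditions are ordinary function values. Fractional
orders encode power-law memory: lowering an order makes that population's
response more history-dependent and widens the stable sector of its
equilibria.

Assumptions worth keeping in mind: no treatment terms, no innate
(nonspecific) immune compartment (the model targets chronic infection /
tumour settings in which that compartment has already failed), no
stochasticity, exactly two populations. A viability flag `μ/ν > δ`
(saturated T-cell growth beats death) is computed and reported but does
not gate construction; equality counts as a violation.

Units as printed in the source parameter tables are carried verbatim:
`a` and `ν` are treated as bare numerics even though their tabulated
units (cell⁻¹·day⁻¹) are not dimensionally consistent with their role
inside the type-II denominators. No dimensional validation is attempted.

## Equilibria and existence

`E0 = (0,0)` and `E1 = (Λ,0)` always exist. The interior point is taken
in closed form, `P* = δ/(μ−νδ)`, `T* = β_P(1−P*/Λ)/(c/(1+aP*))`, and is
flagged biologically existing iff `μ−νδ > 0` and `P* < Λ` (strict).
Degenerate cases are total, never raised: `μ−νδ = 0` reports undefined
coordinates with a "degenerate denominator" trace; `P* = Λ` (where E2
coincides with E1) is flagged nonexistent with the coincidence recorded.

## Stability classification

For rational orders `α₁ = k₁/m₁`, `α₂ = k₂/m₂` (stored as exact reduced
fractions; decimal input is snapped by continued-fraction approximation
with maximum denominator 1000) and `m = lcm(m₁, m₂)`, the eigenvalue
problem at an equilibrium is `det(diag(λ^{mα₁}, λ^{mα₂}) − J) = 0`, a
polynomial of integer degree `m(α₁+α₂)`. The equilibrium is LAS when all
roots satisfy `|arg λ| > π/(2m)`.

Implementation choices:

* **E0 and E1 analytically.** Their problems factor into
  `λ^{mαᵢ} = const`: E0 always has a positive real root (`λ^{mα₁} = β_P`),
  hence is always unstable; E1 is LAS iff `μΛ/(1+νΛ) < δ` (equivalently
  `δ/(μ−νδ) > Λ` when `μ−νδ > 0`), with the boundary counted unstable.
  The closed forms avoid numerical fragility; the root-finding path is
  still run on E0/E1 (and checked for agreement in tests).
* **E2 by root-finding.** The sparse polynomial (exponents `m(α₁+α₂)`,
  `mα₂`, `0`) is expanded densely and solved via the companion matrix
  (`numpy.roots`). Roots with `|Im| < 1e-10·max(1, |Re|)` are snapped to
  the real axis before arguments are taken, because `arg` is
  discontinuous there and an un-snapped conjugate pair straddling the
  axis could flip a verdict. Principal arguments use the convention
  `(−180°, 180°]`.
* **Marginality.** `|min|arg| − 90/m| < 1e-8°` yields verdict
  `marginal`; the sector theorem is silent on the boundary and we do not
  guess.
* **Equal orders.** For `α₁ = α₂ = α` the 2×2 eigenvalue problem is used
  directly (`|arg z| > απ/2` on the Jacobian eigenvalues), with the two
  closed-form criteria reported alongside: the Routh–Hurwitz branch
  (`A₁(A₂+1) − 1 < 0` ⇒ LAS for every order) and the half-angle arccos
  criterion, whose argument equals `cos(2·arg z)` for the complex pair —
  when that argument falls outside `[−1, 1]` the report says "criterion
  inapplicable" rather than inventing a verdict. The general Routh–
  Hurwitz alternative for the *transformed* multi-order polynomial is not
  implemented: it is not well specified for sparse high-degree
  polynomials, and the sector condition is complete on that path.
* **Angle equation.** As a cross-check, every computed E2 root argument
  is substituted into the polar-form angle relation obtained by
  eliminating the modulus `r` from the characteristic equation. The
  fractional powers are evaluated through the ratio
  `sin(mα₂θ)/sin(m(α₁+α₂)θ)`, which is positive at genuine roots (it
  equals `r^{mα₁}` over the middle coefficient); angles where the
  relation is singular or the ratio nonpositive are skipped and flagged,
  as are real roots at `θ = 180°`.

## Fractional time stepping

The simulator is an Adams–Bashforth–Moulton predictor–corrector for
Caputo systems, generalised to component-wise orders: each component uses
its own fractional convolution weights (product-rectangle predictor,
product-trapezoidal corrector) over the full, untruncated history.
Defaults: step `h = 0.01` days, one corrector pass; both configurable. A
sliding memory window (short-memory principle) exists as an opt-in
approximation and is off by default — correctness over speed at
desk-scale horizons (the cost is quadratic in the number of steps; the
packaged 300–400-day scenarios take seconds). With `α = 1` the scheme
reduces to a second-order classical predictor–corrector, which is how it
is validated against `scipy.integrate.solve_ivp`.

Negative undershoots are never clipped (clipping would silently change
the dynamics); the worst excursions are recorded in the trajectory
metadata, and the packaged scenarios stay above `−1e-6`. Non-finite
states abort the integration with the truncated trajectory and the abort
index returned.

The scalar analytic yardstick is the Mittag-Leffler function:
`E_α(−t^α)` solves `D^α y = −y, y(0)=1`. `mittag_leffler` sums the power
series in log space in float64 and falls back to an arbitrary-precision
(mpmath) summation when alternating-series cancellation would cost more
than about four digits; on the `|z| ≲ 5` oracle range it is accurate to
better than `1e-10`.

### Qualitative outcome classification

Because no reference integrator, step size or horizon exists for the
published trajectory figures, long-run behaviour is asserted
qualitatively. Over a trailing window (default 50 days; a trajectory
must cover at least twice the window):

* `converged_to(label)` — the state stays within a ball of radius
  `0.01·(1 + |eq|∞)` around one biologically existing equilibrium;
* `oscillatory` — trailing peak-to-trough amplitude of `P` exceeds 5% of
  its trailing mean without convergence;
* `diverged` — non-finite values or magnitudes beyond `1e8`;
* `undecided` — otherwise.

The three packaged scenarios realise their stability verdicts:
`scenario1 → converged_to(E1)`, `scenario2 → oscillatory` (E2 exists but
fails the sector condition; limit cycle), `scenario3 → converged_to(E2)`.

## Scenario fixtures and problem sizes

The packaged scenarios carry the canonical parameter columns
(`scenario1`: β_P=2.4, Λ=1, c=4, a=0.2, μ=3.98, ν=1.9, δ=1.99, α=(9/10,
3/4); `scenario2`: Λ=10, a=4, μ=3.9, ν=1.9, δ=1, α=(4/5, 3/5);
`scenario3`: Λ=5, a=1, otherwise as scenario2), all from
`(P₀, T₀) = (0.3, 0.01)`. Horizons are 400, 400 and 300 days — past the
reported settling times (≈200 days for scenario 1, ≈100 for scenario 3)
with margin for the slow algebraic tails of fractional relaxation.

Test problem sizes are chosen to keep the quadratic-memory integrator
cheap while still probing every property: the full-horizon simulations
run once per test session and are shared; the step-halving
(grid-refinement) invariant is asserted over the 40-day transient, where
the solution varies fastest and discretisation error is largest; the
integer-order-limit comparison uses contracting dynamics at `t ≤ 20`
(on a dynamically unstable spiral, pointwise agreement with any reference
integrator degrades exponentially regardless of scheme quality, so a
pointwise `1e-4` check is only meaningful where the flow is
non-expanding).

What the synthetic scenarios do *not* emulate: measurement noise,
patient-to-patient parameter variability, treatment, or any spatial
structure — passing tests show the mathematics is implemented correctly,
not that the model fits any particular dataset.

## Known limitations

* The stability theory covers local asymptotic stability only: no global
  statements, no Lyapunov functions, no bifurcation continuation.
* Only two-dimensional systems; orders must be rational in `(0, 1]`.
* The solver is explicit with fixed step: stiff parameter regimes or
  very long horizons would want an implicit or adaptive method, which is
  out of scope.
* Printed-table angle values are reproduced to the precision of the
  table's own printed roots (fourth-decimal differences in the source's
  angles trace to its rounding, not to the classification).
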