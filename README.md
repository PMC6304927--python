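# fracimmune

Dynamics of a pathogen population (typically a tumour or a chronic
infection) under the pressure of the specific adaptive immune response
(memory T cells), modelled with Caputo fractional derivatives of
*different* rational orders for the two populations. The package is for
modellers who want the full qualitative workflow — closed-form equilibria,
multi-order local stability classification, and fractional time stepping —
behind one small API and CLI.

## The model

With pathogen load `P(t)` and memory-T-cell level `T(t)` (cells), the
system is

```
D^α₁ P = β_P P (1 − P/Λ) − (cP / (1 + aP)) T
D^α₂ T = (μP / (1 + νP)) T − δT,        0 < α₁, α₂ ≤ 1
```

where `D^α` is the Caputo derivative, the pathogen grows logistically
(rate `β_P`, capacity `Λ`), is killed through a saturating Holling
type-II response (maximum rate `c`, half-effect level `a`), and T cells
proliferate through a second type-II response (maximum rate `μ`,
half-max load `ν`) and die at rate `δ`. Fractional orders give the
populations memory: the present rate of change depends on the whole
history, with power-law weighting.

The system always has the disease-free point `E0 = (0, 0)` and the
pathogen-only point `E1 = (Λ, 0)`; when `μ − νδ > 0` and
`P* = δ/(μ − νδ) < Λ` it also has the coexistence point

```
E2 = (P*, T*),   T* = β_P (1 − P*/Λ) / (c / (1 + aP*)).
```

Stability is decided through the transformed eigenvalue problem
`det(diag(λ^{mα₁}, λ^{mα₂}) − J) = 0` with `m` the lcm of the orders'
denominators: an equilibrium is locally asymptotically stable (LAS) when
every root satisfies the sector condition `|arg λ| > π/(2m)`. `E0` is
always unstable (the disease never clears on its own); `E1` is LAS
exactly when `δ/(μ − νδ) > Λ`; `E2` is classified by solving its sparse
characteristic polynomial

```
λ^{m(α₁+α₂)} − β_P(A₁(A₂+1) − 1) λ^{mα₂} + β_P δ² A₁ / (μΛ(1−A₁)) = 0,
A₁ = 1 − P*/Λ,  A₂ = aP*/(aP*+1).
```

Trajectories are integrated with a fractional Adams–Bashforth–Moulton
predictor–corrector with component-wise orders and full convolution
memory.

## Worked example

Three scenarios ship with the package (`scenario1`–`scenario3`), covering
immune collapse, sustained oscillation and chronic coexistence, all
starting from `(P₀, T₀) = (0.3, 0.01)`:

```
$ fracimmune report --scenario scenario3
Scenario: scenario3
Immune viability mu/nu > delta                 1.0526 (satisfied)
Equilibrium point E1                           E1(5, 0)
Stability condition of E1                      delta/(mu - nu*delta) = 0.5 <= Lambda = 5 (E1 is unstable)
Equilibrium point E2                           E2(0.50, 0.81)
Parameter A1                                   0.9000
Parameter A2                                   0.33333
Least common multiple of order denominators    5
Characteristic equation of eigenvalues for E2  λ^7 - 0.4800*λ^3 + 1.1077 = 0
Eigenvalues for E2                             0.9287+0.3757i; 0.9287-0.3757i; 0.1852+1.0410i; 0.1852-1.0410i; -1.0798; -0.5741+0.7646i; -0.5741-0.7646i
Angle of eigenvalues for E2                    22.0260; -22.0260; 79.9103; -79.9103; 180.0000; 126.8984; -126.8984
Stability condition of E2                      min |theta| = 22.0260 deg vs 18.0000 deg (E2 is LAS)
Initial conditions                             (0.3, 0.01)
```

Reading: the orders 4/5 and 3/5 share denominator lcm `m = 5`, so the
stable sector is `|arg λ| > 90/5 = 18°`. The degree-7 polynomial's
smallest root angle is 22.03° > 18°, hence the coexistence point
(tumour 0.5, T cells 0.81) is LAS — tumour and immune response persist
together at a bounded level. Simulating confirms it:

```
$ fracimmune simulate --scenario scenario3
scenario3: final state (0.5143, 0.8149) at t = 300; outcome: converged_to(E2)
```

In `scenario2` (capacity Λ = 10) the smallest angle is 14.32° < 18°: E2
is unstable and the populations orbit a limit cycle. In `scenario1` the
T cells cannot sustain themselves (`δ/(μ−νδ) = 10 > Λ = 1`): E1 is LAS
and the tumour grows to its carrying capacity.

The same objects are available from Python:

```python
import fracimmune as fi

cfg = fi.load_scenario("scenario3")
e0, e1, e2 = fi.equilibria(cfg.params)
rep = fi.classify(cfg.params, e2)
print(rep.verdict, rep.min_abs_arg_deg, rep.threshold_deg)
# LAS 22.026 18.0
traj = fi.simulate(cfg.params, cfg.y0, t_end=300, h=0.01)
print(fi.qualitative_outcome(traj, [e0, e1, e2]))
# converged_to(E2)
```

Custom parameter sets go in a flat YAML file using the model's symbol
names (`beta_P, Lambda, c, a, mu, nu, delta, alpha1, alpha2, P0, T0,
t_end, h`) and are passed with `--config`.

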