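# Methods

## Model and assumptions

`wpmdyn` implements a deterministic, well-mixed compartment model for plastic
waste in an ocean system. The state (W, M, R) — waste plastic, marine
debris, recycled material — evolves by

```
W' = λ − γW − βMW + μR
M' = βMW − αM
R' = γW + αM − (μ + θ)R
```

Assumptions: homogeneous mixing (the only nonlinearity is the bilinear
contact term βMW), time-constant rates, no delays, no spatial structure, no
stochasticity. Amounts are treated as dimensionless positive reals — no
unit system is attached to the compartments, and the rates are interpreted
per unit of the same (unspecified) time unit. Summing the equations gives
the bookkeeping identity (W + M + R)' = λ − θR: material enters only through
new production and leaves only as permanent loss from the recycling pool.

The non-negative octant Ω is positively invariant. `ParameterSet` rejects
non-positive rates at construction because every closed form below divides
by γ, θ, α or β; degenerate (zero-rate) variants are out of scope rather
than special-cased. The right-hand side itself accepts transiently negative
states so that adaptive integrators can probe across the axes; stored
trajectories are instead post-checked against a floor of −1e−8.

## Threshold analysis

Both equilibria share R̄ = λ/θ. The basic reproduction number is computed
two ways: the closed form BR = βλ(μ+θ)/(αγθ), and a next-generation-matrix
route that symbolically differentiates the debris generation term F = βMW
and removal term V = αM at the debris-free equilibrium and takes the
spectral radius of f·v⁻¹. The second route exists so that the closed form
is genuinely cross-checked by differentiation rather than by substituting
itself; the two agree to 1e−10 relative on randomized parameter sets.

The positive equilibrium satisfies M* = (γ/β)(BR − 1), so it exists exactly
when BR > 1. |BR − 1| < 1e−9 is reported as the threshold case
(`exists=False, at_threshold=True`) since there the positive branch
coincides with the debris-free one. Published component orderings for these
points are inconsistent, so equilibria always carry *named* components
(W, M, R) and are printed with labels, never as bare tuples.

## Stability

Local classification uses the eigenvalues of the analytic Jacobian with a
tolerance of 1e−9 on real parts; |Re λ| below the tolerance is classified
`marginal` rather than silently rounded. At the debris-free state the
Jacobian block-decouples into the scalar βW⁰ − α (sign given by BR − 1) and
a 2×2 (W, R) block whose trace −(μ+θ+γ) and determinant γθ are sign-definite,
which is the Routh–Hurwitz argument behind the threshold dichotomy.

Global stability of E* is certified by the Lyapunov function

```
L = θ/2 (R − R*)² + α/2 [(W − W*) + (M − M*) + (R − R*)]²
```

whose orbital derivative, using the equilibrium relations, is

```
dL/dt = (γ − α)θ (W − W*)(R − R*) − ((μ+θ)θ + αθ)(R − R*)².
```

For α = γ the cross term vanishes and dL/dt ≤ 0 with equality only at
R = R*, so LaSalle's principle applies. The package computes dL/dt by the
chain rule (gradient of L contracted with the vector field) so it remains
meaningful for exploratory use when α ≠ γ, and asserts agreement with the
closed form to 1e−8 in tests; the certificate itself is only claimed for
α = γ. Whether E* is globally stable when α ≠ γ is an open question:
`verify_global_convergence` provides seeded ensemble *evidence* (n random
strictly positive starts, integrate, count arrivals within tolerance), and
is documented as a surrogate, never a proof.

Ensemble defaults — 20 starts, horizon 500, convergence tolerance 1e−3
(infinity norm), initial box [0.1, 5]³ — are user-settable defaults chosen
so that both worked-example rate sets converge robustly; the box covers the
worked-example initial point (1.5, 2, 1) while excluding the axes, since
the Lyapunov domain requires strictly positive states.

## Bifurcation

With β as bifurcation parameter, BR = 1 at β* = αγθ/(λ(μ+θ)). At
(E⁰, β\*) the Jacobian has a simple zero eigenvalue; the right and left
null eigenvectors are computed numerically from the Jacobian and its
transpose (an internal-consistency error is raised if no eigenvalue lies
within 1e−9 of zero), oriented as u = (−α, γ, 0) and normalised so
v·u = 1, giving v = (0, 1/γ, 0). The only curvature of the field is the
bilinear term, so the center-manifold coefficients are analytic:

- `full_sum` (default): a = −2αβ\*, the symmetric double sum counting both
  orderings of each mixed derivative pair;
- `single_term`: a = −αβ\*, counting each unordered pair once — the value
  usually quoted for this model.

Both conventions give b = λ(μ+θ)/(γθ) = W⁰ > 0 and a < 0 for every valid
parameter set, so the classification is always `forward`: the positive
branch emerges supercritically, with no bistability or hysteresis. A
finite-difference contraction of the Hessians cross-checks the analytic
coefficients in the tests. (In the source derivation one mixed-derivative
label reads f₁ where the mathematics requires f₂; the implementation
follows the mathematics — only f₂ has curvature reaching the left
eigenvector.)

The bifurcation diagram integrates from the fixed initial state (1.5, 2, 1)
for each β on a grid (β = 0 is allowed and handled as pure debris decay)
and reports the mean of M over the final 10 % of the horizon next to the
analytic branch max(0, (γ/β)(BR − 1)). The default horizon is 4000 time
units: just above β* the slow eigenvalue scales like αβ\*·M*, and at β*
itself the decay is algebraic, so a long horizon is needed for the tail
mean to settle to diagram accuracy (1e−3); at the exact threshold point
the tail mean is only approximately zero (~1e−3 at horizon 4000).

## Sensitivity

Normalized forward sensitivity indices (elasticities) of BR are closed
form: +1 for β and λ, −1 for α and γ, ±μ/(μ+θ) for μ and θ. They cancel in
pairs (β/α, λ/γ, μ/θ), reflecting BR's log-derivative structure. A central
finite difference with relative step 1e−6 (absolute fallback below 1e−6)
cross-checks each index to 1e−6. `perturb_scenario` reports both the exact
recomputation of BR under a percentage change and the first-order estimate
BR·(1 + SI·pct/100): for β and λ the two coincide exactly; for θ they
differ at second order. Note a known discrepancy in the published worked
example for θ +20 % at the tabulated rates: the quoted value 34.8763
matches neither the exact recomputation (36.1429) nor the first-order
estimate (34.8857); this scenario is therefore reported but not used as a
regression value.

## Numerical choices

- Integrator: DOP853 (adaptive high-order explicit Runge–Kutta), rtol 1e−8,
  atol 1e−10; reporting on a uniform 1000-point grid decoupled from the
  internal steps. Halving the tolerances moves worked-example final states
  by far less than the 1e−3 convergence tolerance.
- Seeding: one integer seed drives all initial-condition draws through
  `numpy.random.SeedSequence` child streams, one per run, so enlarging an
  ensemble appends draws without reshuffling earlier ones.
- Config files (YAML or JSON) round-trip the rates at full float precision;
  trajectory CSVs store t, W, M, R at repr precision.
- Integrator failures are reported (per run / per grid row), not raised, so
  sweeps and ensembles degrade gracefully.

## Limitations

- Constant rates: no seasonality (e.g. periodic contact rate), delays,
  spatial transport, or stochastic forcing.
- The global-stability certificate for E* requires α = γ; outside that case
  only empirical convergence is reported.
- The sensitivity analysis covers BR only, not the components of E*, and is
  local (elasticities), not a global variance-based method.
- Simulated "long-run" levels are finite-horizon tail statistics; very close
  to the threshold they carry the slow-relaxation error discussed above.
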