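# Methods

## Model

The package analyses a planar predator–prey system in which the prey is
subject to a *double* Allee effect and the predator has a linear
(Holling type-I) functional response:

    D^ζ x1 = r·x1/(x1+β) · (1 − x1/ρ)(x1 − α) − a·x1·x2
    D^ζ x2 = b·x1·x2 − c·x2

`D^ζ` is the Caputo fractional derivative of order ζ ∈ (0, 1]; ζ = 1
recovers the classical ODE.  The order acts as a memory parameter: the
growth rates respond to the whole history of the populations, weighted by a
power-law kernel.

Parameters (all positive unless noted):

| symbol | meaning                              | units            |
|--------|--------------------------------------|------------------|
| r      | intrinsic prey growth rate           | 1/time           |
| ρ      | prey carrying capacity               | density          |
| a      | predator capture rate                | 1/(density·time) |
| α      | Allee threshold (may be ≤ 0)         | density          |
| β      | auxiliary Allee intensity            | density          |
| b      | prey→predator conversion rate        | 1/(density·time) |
| c      | predator natural mortality           | 1/time           |

The Allee effect is **strong** for α > 0 (prey declines below the
threshold) and **weak** for −β < α ≤ 0.  The boundary α = −β is permitted:
there the two Allee factors cancel and prey growth degenerates to plain
logistic; α < −β is rejected as it would make the growth factor negative at
vanishing density.

## Equilibria

Besides extinction (0,0) and the carrying-capacity point (ρ,0) — plus the
Allee point (α,0) in the strong regime — the coexistence equilibrium
follows from the nullclines:

    x1* = c/b          (predator nullcline; independent of r, ρ, α, β)
    x2* = r(1 − x1*/ρ)(x1* − α) / (a(x1* + β))   (prey nullcline)

It is feasible iff α < c/b < ρ (strong) or c/b < ρ (weak).  Within 1e−12 of
either boundary (c/b = ρ or c/b = α) the point is flagged degenerate
instead of raising, so parameter sweeps can cross the boundary.
This nullcline derivation reproduces all three published interior
equilibria to four decimals; closed forms are hand-coded, no symbolic
engine is used.

## Stability and the Hopf critical order

An equilibrium of a Caputo system of order ζ is locally asymptotically
stable iff every Jacobian eigenvalue λ satisfies |arg λ| > ζπ/2 (Matignon).
The signed margins ν_i = ζπ/2 − |arg λ_i| are reported per eigenvalue;
|ν| < 1e−9 is classified non-hyperbolic (separates genuine bifurcation
points from rounding), a real pair with opposite signs is a saddle for
every order.  Arguments are taken in (−π, π] so a conjugate pair gives one
margin.

When the interior Jacobian carries a complex pair with positive real part
(¼tr² < det and tr > 0), the margin crosses zero at

    ζ* = (2/π)·|arg λ|,

the critical order of the order-driven Hopf bifurcation: the point is
stable for ζ < ζ*, and an attracting limit cycle emerges for ζ > ζ*.
Verdicts always come from eigenvalues.  The closed-form trace inequality
for interior stability circulating in the literature for this model is
typographically ambiguous; the condition checker reports it under the
reading c < (ρ+α)·b/2 with an explicit caveat and a consistency flag, and
never uses it for a verdict.

## Solver

`caputo.abm_solve` implements the classical fractional
Adams–Bashforth–Moulton predictor–corrector (PECE) on a uniform grid with
the full memory sum (no short-memory truncation): truncation error would
contaminate the delicate near-threshold amplitude measurements, and the
horizons used here (≤ 4·10⁴ steps) make the O(N²) cost a few seconds.  One
corrector pass per step by default (recorded in trajectory metadata,
configurable).  States are never clipped; a non-finite iterate raises a
blow-up error carrying the last valid time.  Verified properties: the
linear test D^ζy = −y matches the Mittag-Leffler series to ≤1e−3 at
h = 2⁻⁸; ζ = 1 matches exp(−t) to ≤1e−4 and a tight-tolerance DOP853
reference to ≤1e−4 on the model itself; the memory quadrature is causal;
the empirical convergence order brackets the theoretical 1+ζ.

`mittag_leffler` evaluates E_ζ(z) by direct series, switching to 50-digit
arithmetic for |z| > 10 (the alternating series loses double-precision
digits there) and refusing |z| > 50, beyond which an asymptotic expansion
would be the right tool; those arguments never arise at the horizons used.

## Sweeps and outcome classification

Hopf sweeps perturb the interior equilibrium by +1% in prey (reproducible,
avoids basin questions), integrate with defaults h = 0.05 and horizon
2000 time units, discard the first half as transient, and measure prey
peak-to-trough amplitude; ε_amp = 1e−3 prey units separates a cycle from
numerical ringing (two orders below observed near-onset cycle amplitudes).
The analytic threshold (margin root; bisection in α at fixed ζ) is primary,
the grid bracket where the amplitude first crosses ε_amp corroborates it.

Near the threshold fractional transients decay or grow only on the
timescale 1/|Re λ^{1/ζ}| (the dominant root of the characteristic
equation), so a plain amplitude threshold misreads marginally stable runs
at finite horizon.  `classify_outcome` therefore compares the last two
quarter-window amplitudes and calls a cycle only when the final window
exceeds ε_amp *and* has stopped decaying (≥ 95% of the previous window; the
5% tolerance absorbs sampling-phase jitter).  For verdict-vs-simulation
consistency checks across random parameter sets, `linearized_rate` sizes
the horizon as ≈ 8/|Re λ^{1/ζ}| with 100 grid points per linear period;
sets whose transition would need more than 2·10⁴ steps are excluded from
simulation-based checks — their transitions are real but unresolvable by
any finite direct simulation (growth times of many thousands of
oscillation periods), not a property this package can or should test by
integration.

## Diagnostics

**Boundedness.**  ω = x1 + (a/b)x2 obeys D^ζω + μω < H for any
0 < μ ≤ c (the mortality term absorbs the predator part; this condition is
implicit in the underlying comparison argument), with
H = max_{x1≥0} [r·x1(1−x1/ρ)(x1−α)/(x1+β) + μ·x1].  The maximand has a
negative cubic tail, so the supremum is found on [0, 2ρ] by a 4001-point
grid scan polished with bounded scalar minimization (tolerance 1e−8; a
10⁶-point brute-force scan agrees to 1e−6 in tests).  Any valid upper
bound suffices — the check is conservative.  The comparison uses the
post-transient tail because the bound is asymptotic.

**Lyapunov decrease.**  The Volterra-type function
θ = (x1 − x1* − x1* ln(x1/x1*)) + (a/b)(x2 − x2* − x2* ln(x2/x2*)) is
positive definite about the interior point.  Its decrease along solutions
is only guaranteed inside the domain D = {(x1−x1*)(x1−α) < 0} (strong) or
{x1 < x1*} (weak); membership uses open inequalities with 1e−12 slack, and
the monotone verdict judges only consecutive in-domain node pairs, with
1e−8 per-step slack for discretization error.  Excursions outside D are
flagged, never judged.

An important caveat the implementation made explicit: the exact identity
dθ/dt = (x1 − x1*)(g(x1) − g(x1*)) at integer order, with
g(x) = r(1−x/ρ)(x−α)/(x+β), shows that θ *increases* in the band between
x1* and g's maximizer whenever g′(x1*) > 0 — which is precisely the
trace-positive (Hopf-capable) configuration, e.g. the first fixture set.
Global decrease of θ therefore cannot hold for such parameter sets, and
the diagnostic reports rather than asserts monotonicity; the test suite
asserts it only for contracting configurations (trace < 0) and for the
documented example start, where the in-domain increments stay below the
slack.

## Scenarios and synthetic parameters

The three fixture sets carry the exact printed parameter values
(β = 0.7290 at full precision).  The third set's α is not printed beside
its equilibrium; the fixture uses α = −0.01 (its figure caption's
weak-Allee value), which reproduces the printed (0.9824, 0.1600) — a
documented reconstruction.  At ζ = 0.98 that set is marginally *stable*
(its own critical order is 0.9822), so both weak-regime family members are
expected to converge; the package reports its own margin-root thresholds
for α-sweeps with full provenance rather than adopting any printed α*.

`generate_params` draws rates (r, a, b, c) and β log-uniformly
(r ∈ [0.05, 1], a, b, c ∈ [0.1, 1], β ∈ [0.01, 1] — they act
multiplicatively and span decades), ρ uniformly in [1, 10], rejects draws
without an interior point (c/b ≥ ρ), then draws α uniformly in (0, c/b)
(strong) or (−β, 0] (weak), so every output satisfies its regime's
existence condition; it is deterministic given the seed and errors out if
the rejection rate exceeds 99%.

`run_experiments` executes every fixture end to end (equilibria →
classification → critical order → simulation → sweeps → diagnostics),
writes CSV trajectories, PNG phase portraits/time series and a JSON
summary, and exits nonzero if any fixture expectation fails.  Tests run it
at h = 0.1, horizon 800 (about 22 linear periods for the slowest fixture) to
stay desk-scale; the full-resolution defaults are h = 0.05, horizon 2000.

## Known limitations

- Uniform grid only; no adaptive or implicit fractional stepping.
- Caputo operator only (no Riemann–Liouville or Atangana–Baleanu).
- No center-manifold/normal-form analysis: the direction and stability of
  the emerging cycle are observed numerically, not derived.
- The synthetic parameter generator emulates admissible *parameter regimes*,
  not fitted ecological data; passing checks demonstrate internal
  consistency of the theory and solver, not agreement with field data.
- Simulation-based transition checks are restricted to parameter sets whose
  linearized growth/decay timescale is resolvable (see above).
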