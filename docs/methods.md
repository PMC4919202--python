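# Methods

## The models

`langdyn` studies the competition of two languages through the frequencies
`u1(x, t)`, `u2(x, t)` of their speaker populations. Four planar models are
implemented, all built from logistic growth plus an interaction term:

1. **hybrid_lv** — Lotka–Volterra growth with a one-way conversion term
   (`+c·u1·u2` gained by language 1, `−c·u1·u2` lost by language 2): the
   classic "stronger language attracts the weaker's speakers" picture,
   without space.
2. **basic_rd** — the same reaction terms with Fickian diffusion
   `d_i Δu_i`; the reaction part, hence the equilibrium/stability analysis,
   is identical to the hybrid model, so both variants share one reaction
   kernel and differ only in the diffusion switch.
3. **common_capacity_rd** — one-way conversion, but each logistic term
   saturates against the capacity left by the rival:
   `a1·u1·(1 − u1/(K − u2))`.
4. **ecology_society** — the bidirectional model:

   ```
   ∂u1/∂t = d1 Δu1 + a1 u1 (1 − u1/K1 − α u2/K1) + c1 u1 u2
   ∂u2/∂t = d2 Δu2 + a2 u2 (1 − u2/K2 − β u1/K2) + c2 u1 u2
   ```

   The Lotka–Volterra part (α, β) carries the *ecological* competition for
   speakers; the attractiveness rates c1, c2 carry the *social* status of
   each language (media, policy, prestige). Because both c's are positive,
   neither language is stronger by construction, which is what makes
   coexistence and even co-development possible outcomes.

All frequencies are dimensionless densities; rates are per unit time;
diffusivities are area per time on the unit square. No unit-conversion layer
exists.

### Conventions at removable singularities

For the common-capacity model every term that divides by `K − u_j` carries a
factor `u_i`, so at states where a species is absent the 0/0 limit is taken
as 0 (this is also the convention under which the closed-form linearization
matrices at `(K, 0)` and `(0, K)` hold). A denominator with
`|K − u_j| < 1e-9·K` and a *nonzero* opposing numerator raises a
singular-state error; negative denominators evaluate algebraically, since
the analysis itself probes interior candidates with `u1* + u2* > K`.

`reaction_rates` and `reaction_jacobian` deliberately do not reject negative
coordinates: infeasible equilibrium candidates are classified too (the
analysis needs their character), and non-negativity of *fields* is the PDE
stepper's job.

## Stability classification

`pq_stability` implements the planar trace/determinant test: with
`p = −tr A` and `q = det A` at an equilibrium, `p > 0 ∧ q > 0` is
asymptotically stable and `p < 0 ∨ q < 0` is unstable — exactly the planar
Routh–Hurwitz condition. Sign decisions use a relative tolerance of
`1e-12 × max|A|`: every quantity entering A is exact algebra on the
parameters, so only floating-point noise needs absorbing. `|p| ≤ tol` or
`|q| ≤ tol` (with neither strict condition met) is reported as
`non_hyperbolic`, because the linear test is inconclusive there. The
center-like case `p = 0, q > 0` — which the common-capacity interior roots
always produce — additionally carries `paper_verdict="not stable"`: such a
state is not asymptotically stable, but the strict "unstable" label would
overclaim. When `p ≈ 0` comes with `q < 0` the state is genuinely unstable
(real eigenvalues `±√(−q)`), and is labeled so; the eigenvalue oracle
`eigen_stability` (numpy eigvals) is kept as an independent cross-check and
agrees everywhere off the tolerance boundary.

## Closed-form equilibria and feasibility windows

Each variant's candidate list is evaluated from the printed closed forms
(origin, two single-language states, and one or two interior roots — the
common-capacity model's interior pair comes from a quadratic, labeled by its
± discriminant branch). A complex discriminant yields NaN coordinates with a
`discriminant_complex` flag rather than an error. Every returned candidate is
certified in tests by `numeric_equilibrium_residual` (max-norm of the
reaction rates) at `≤ 1e-12·max(a1, a2)`. The certification draws exclude
ill-conditioned parameter sets — candidates with coordinates beyond
magnitude 10 (a near-degenerate interior denominator inflates the closed
form) or shared-capacity denominators within `1e-3·K` of zero — because
there float64 cancellation exceeds any absolute residual bound even for an
exact root; the formulas themselves are exact algebra either way.

`interior_feasibility` evaluates the admissibility inequalities:

* one-way models: interior positivity ⇔ `K1 < a2/c`;
* common-capacity: real roots need `K > 2√(a1a2)/c`; the minus root is
  positive only on `(2√(a1a2)/c, (a1+a2)/c)` with `a2 > a1`, and there the
  capacity check fails (`u1*+u2* ≥ K`, equality only at the right endpoint),
  by monotonicity of `φ(x) = x + (a2 − a1 − √(c²x² − 4a1a2))/c` — so a
  shared ceiling alone never yields feasible coexistence;
* bidirectional model: the admissible K1 window splits on the sign of
  `s = c2·K2 − β·a2` (an exact-zero s raises a boundary-case error). With
  `αβ < 1` — the realistic competition regime, and the one the random-draw
  tests sample — the window coincides with exact positivity of the interior
  coordinates, which the tests verify by brute force on 500 draws. The
  simplified `α > c1/a1` reduction for K1 = K2 = 1 is exposed only as a
  diagnostic field: it fails for the matched-languages experiment even
  though the full inequality holds, so it cannot be part of the verdict.

Both experiments' stable interior equilibria have `u2* > K2` (the
attractiveness terms push a language beyond its own carrying capacity);
this is recorded as-is, never clamped.

## The PDE solver

Vertex-centered n×n grid on `[0,1]²` (default n = 51, h = 0.02; no grid is
prescribed by the source analysis, and refinement tests show < 2% change in
summary extrema between n = 33 and n = 65). The Laplacian is the 5-point
stencil with mirror ghost nodes, which realizes the zero-flux boundary
condition `∂u/∂n = 0` and makes pure diffusion exactly conservative under
trapezoid quadrature (verified to 1e-10 relative over 10⁴ steps). Time
stepping is explicit forward Euler with the bound
`dt ≤ 0.9·h²/(4·max(d1, d2))` enforced at configuration and stepping time;
the default dt = 0.005 sits comfortably under the bound for both presets
(bounds 0.009 and 0.018) and gives O(1e-7) agreement with a high-accuracy
reference ODE integration in the spatially homogeneous limit at t = 700.
Snapshots are taken at the first completed step at or past each requested
time. Field values dipping below zero by at most 1e-12 (roundoff) are
clamped to zero and counted in the debug log; larger negatives or
non-finite values abort with the step index.

## Synthetic initial conditions

The published initial fields exist only as figures, so they are emulated: a
smooth shape (`bump` = squared-exponential, `plateau_bump` =
super-Gaussian with a flat top, or `smoothed_noise` = seeded white noise
under a Gaussian filter) is synthesized and affinely rescaled so its exact
grid extrema equal the documented t = 0 ranges — experiment 1: u1 ∈
(0.0, 0.9), u2 ∈ (0.0, 0.3); experiment 2: both ∈ (0.2, 0.6). Bump centers
(0.3, 0.3) / (0.7, 0.7) and width 0.15 are package conventions, chosen to
give well-separated strongholds. Consequences: the summary tables produced
here are comparable to the published ones only at the level of qualitative
patterns (monotone minima, survival, late dominance), and passing those
checks says nothing about digit-level values of any particular empirical
run — nor about real speaker-census data, which the generator does not
attempt to emulate (no demography, no geography, no noise in the dynamics).

## Known limitation: the unequal-languages experiment's min-u1 pattern

With the printed parameters taken at face value, language 1 in experiment 1
relaxes to its nullcline within t ≈ 100 (rate a1 = 0.08) while language 2
needs t ≈ 300 to grow (rates 0.01–0.02). The field minimum of u1 therefore
overshoots (≈ 0.96 at t = 100) and then descends to the coexistence value
0.79295: *not* monotone over the schedule {0, 100, 300, 500, 700}. This is
parameter-intrinsic — the homogeneous ODE shows the same overshoot, and a
reaction–diffusion front (speed ≈ 2√(d1·a1) ≈ 0.02 per time unit) fills any
u1 ≈ 0 region well before the overshoot window closes, so no admissible
initial geometry avoids it. The published table, whose unstated
discretization evolves several times slower than the printed rates imply,
shows the rising phase only. The robust, geometry-independent patterns —
monotone growth of the weak language's minimum, its survival, monotone
minima of both species in the matched experiment, and late dominance of the
socially stronger language — are the ones asserted by the module tests; the
full published claim is asserted verbatim in the acceptance suite and the
min-u1 clause fails there, by design rather than by accident.

## Problem sizes used in tests

Random-draw cross-checks use 100–1000 draws as stated above. PDE module
tests run on n = 17–33 grids with correspondingly larger stable time steps;
the two packaged experiments run once per session at full scale (n = 51,
dt = 0.005, t = 700, i.e. 140 000 steps). The robustness-to-geometry test
varies bump centers in [0.25, 0.4]² / [0.6, 0.75]² and widths in
[0.1, 0.2] on an n = 26 grid.
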