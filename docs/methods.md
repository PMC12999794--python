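# Methods

## Model and assumptions

The package analyses a two-population, two-strategy evolutionary game
between drugstores (recycle expired drugs or not) and residents
(participate or not). Populations are infinite and well mixed; individuals
are boundedly rational and revise strategies by imitation, which yields the
standard replicator dynamics on the unit square in the state (φ, Ω) of
cooperation probabilities:

    dφ/dt = φ(1−φ)[Ω(s−c₂−m) − c₁]
    dΩ/dt = Ω(1−Ω)[φ(m−t₁+t₂) − t₂]

All payoffs are dimensionless "yuan-equivalent" utility units; time losses
t₁, t₂ enter directly as utility penalties with no separate conversion
factor. The model deliberately has no government player: it describes the
market situation in which take-back runs on drugstore and resident
incentives alone.

One modelling subtlety is worth recording. A drugstore's expected utility
of running the programme must weight the cooperative payoff s−c₁−c₂−m by
the *opponent's* strategy probability Ω (the bimatrix row expectation), not
by its own φ; some derivations of this game circulate with the φ-weighted
form, which is inconsistent with the payoff bimatrix and with the replicator
equation that is then stated. This package implements the Ω-weighted form
throughout; a property test asserts exact agreement between the expected
utilities and the brute-force bimatrix row expectation, and between the
utility advantage and the bracket of the vector field.

## Equilibria and stability

The corners E1(1,1), E2(0,1), E3(0,0), E4(1,0) are always fixed; the mixed
point E5 = (t₂/(m−t₁+t₂), c₁/(s−c₂−m)) is reported whenever its
denominators are nonzero and counts as a fifth equilibrium only when both
coordinates are strictly inside (0,1) (margin 1e−12; a boundary-coincident
E5 duplicates a corner and is flagged inadmissible and left unclassified).

Classification uses Lyapunov's indirect method on the closed-form Jacobian.
A point is an ESS when both eigenvalue real parts are negative, a source
when both are positive, a saddle when the determinant is negative, and
non-hyperbolic when any |Re λ| < 1e−9 — an absolute tolerance chosen so
that instances sitting numerically on a bifurcation boundary are flagged
rather than silently classified either way.

At the corners the Jacobian is diagonal, giving closed-form eigenvalues:

    E1: −(s−c₁−c₂−m), −(m−t₁)      E2: s−c₁−c₂−m, t₂
    E3: −c₁, −t₂                    E4: c₁, m−t₁

Structural consequences, all enforced as property tests over random
positive-parameter instances: E2 and E4 are never ESS; E3 is always ESS
(for c₁, t₂ > 0); E1 is ESS iff s−c₁−c₂−m > 0 and m > t₁; an admissible E5
has exactly zero trace and non-positive determinant, hence is never an
attractor. The only possible regimes on strictly positive parameters are
therefore *defection-only* and *bistable*; the regime enum keeps
`E1-only` and `no-ESS` labels for degenerate relaxed instances (c₁ = 0 or
t₂ = 0), where they can arise in the non-hyperbolic sense.

Closed-form Det/Tr "stability condition" tables for this game circulate
with sign slips (the E2 trace omits −m; the printed E5 determinant misses
the φ(1−φ)Ω(1−Ω) factors and its sign; the printed E3 row disagrees with
the diagonal eigenvalues −c₁, −t₂). `symbolic_stability_conditions`
evaluates the printed corner conditions verbatim next to the eigenvalue
verdicts and reports agreement per corner, so the discrepancy is visible
rather than silently corrected; the package's own verdict is always the
eigenvalue one.

## Numerical integration

Trajectories are integrated with LSODA (adaptive, stiff-capable), stepped
manually so the state can be projected back onto the unit square after
every accepted step. Two numerical choices matter:

* **Tolerances.** rel_tol 1e−12, abs_tol 1e−14 by default. The square is
  analytically forward-invariant, so any excursion is integrator local
  error; at these tolerances the measured worst pre-clamp excursion over
  hundreds of random instances is ~4e−13, comfortably inside the 1e−12
  clamping tolerance. Looser tolerances (e.g. 1e−8/1e−10) produce
  excursions around 1e−9, large enough to corrupt the edge dynamics.
* **Open-square clamping.** Excursions are clamped to the *open* square
  (one ulp inside the boundary), not onto it. The boundary edges are
  invariant lines of the dynamics: a trajectory clamped to exactly φ = 1
  can never leave that edge again and may slide into a saddle corner it
  should only graze, silently switching basins. Clamping one ulp inside
  preserves the correct basin while still bounding the excursion. Corner
  *initial conditions* are detected by a zero-field check and returned
  stationary and exact.

Integration stops early once the field magnitude drops below 1e−10, at
which point the state is numerically pinned; the default horizon is 10
native time units (baseline payoff magnitudes of order 10² make convergence
happen well before t = 1). Times are reported in the native time of the
replicator equation; no rescaling to any figure's axis is attempted, since
published trajectory figures for this game use an unreported time scaling.

Convergence is attributed to a corner when the final state is within
eps = 1e−4 (Euclidean) of exactly one corner and the field magnitude there
is consistent with the corner's linearised decay (below eps times the
spectral scale max(1, |λ₁|, |λ₂|) of that corner). The spectral scaling
makes the guard dimensionless: the raw field near a corner is proportional
to the corner's eigenvalues, i.e. to payoff magnitudes, so a fixed small
absolute bound would reject genuinely converged states of any realistically
calibrated instance.

Basins of attraction are estimated by brute force: integrate from every
cell center (i+1)/(R+1) of an R×R interior grid and record the reached
corner. No separatrix is extracted in closed form.

## Sweeps and thresholds

`sweep_parameter` substitutes each value of one parameter, integrates from
a shared initial state (default (0.5, 0.5)) and records the reached
attractor, final state, native convergence time, the instance's ESS set and
regime, and any non-hyperbolic points. `find_threshold` bisects a bracket
[lo, hi] of one parameter until the interval is at most the requested
resolution (default 1 utility unit), reporting the midpoint and both
flanking attractors; an 8-point pre-scan warns if the bracket appears to
contain multiple switches. Thresholds are *operational* — defined by the
attractor reached from the fixed initial state — because that is the
decision-relevant quantity in a bistable game; the structural ESS-existence
boundaries are visible in the same sweep output through the regime column.
At the baseline the operational thresholds are s ≈ 541 (E3 below, E1 above)
and c₁ ≈ 190 (E1 below, E3 above), against structural E1-existence
boundaries of s = 460 and c₁ = 230. Published narrative thresholds for this
game (s ≈ 620, c₁ ∈ (120, 130), c₂ ∈ (200, 210), t ∈ (70, 75),
m ∈ (85, 170)) are mutually inconsistent with the baseline configuration
they are attributed to and are treated as unverifiable annotations, not as
oracles; the package recomputes everything. The published sensitivity
discussion also varies a single "time loss t" where the model distinguishes
t₁ and t₂; the package exposes separate t₁ and t₂ sweeps and defines no
combined t.

## Scenario generation

The only published calibration is a single interview-based point estimate
(s=670, c₁=120, c₂=260, t₁=46, t₂=15, m=80) with no variance information.
The scenario generator therefore samples each parameter independently and
uniformly over an explicit box — the minimal-assumption emulation — with
default ranges [0.5×, 1.5×] of the baseline value, wide enough to bracket
every published one-parameter sweep value. Batches are pure functions of
(seed, n, ranges, regime filter); an optional regime filter uses rejection
sampling capped at 10,000·n draws and fails loudly naming the
regime/ranges pair when the regime is infeasible on the box (as
cooperative-only necessarily is on any strictly positive box). At seed 42,
n = 1000 the default box yields 731 bistable and 269 defection-only
scenarios.

What the generator emulates — and what it does not: it reproduces the
*structure* of plausible calibrations (nonnegative costs and rewards, every
feasible stability regime represented) so every pipeline stage is testable
without survey data. It does not model correlations between parameters
(e.g. promotion-heavy drugstores likely also face higher recycling costs),
heterogeneity within populations, or any empirical distribution; passing
tests on sampled scenarios therefore validate the machinery, not any claim
about real drugstore economics.

## Known limitations

* Exactly two populations with two strategies each; no government player,
  no n-strategy extension.
* ESS here means asymptotic stability of the replicator dynamics; no
  global Lyapunov function or center-manifold analysis is attempted at
  non-hyperbolic points, which are only flagged.
* Basins are grid estimates; resolution-limited near the separatrix.
* Problem sizes in the test suite (grids of 11–21 cells per axis, hundreds
  to a thousand random instances per property) are chosen to make the full
  suite run in about a minute while keeping every regime and boundary case
  exercised.
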