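# Methods

## Model

**Network.** An activity-driven temporal network on a fixed node set of size
`N`.  Each node `u` has an activity potential `a_u ∈ (0,1]`, drawn i.i.d.
from a density `f(a)`.  Per snapshot, `u` activates independently with
probability `a_u`; an active node wires `m` undirected links to partners
drawn uniformly *without replacement* from the other `N−1` nodes.
Self-links are impossible by construction; a pair linked twice in the same
window collapses to one edge (union semantics) — a `multigraph=True` option
keeps multiplicities for sensitivity checks.  The interaction graph for one
evolutionary step is the union `G_δ(t)` of `δ` fresh snapshots; all edges
are discarded afterwards, so windows are independent.  The expected
integrated degree of an activity-`a` node is `(a+⟨a⟩)mδ` as `N → ∞`; at
finite `N` the initiated part saturates,
`N(1−e^{−amδ/N}) + ⟨a⟩mδ·e^{−amδ/N}`, an expression validated against
brute-force simulation in a strongly finite-size regime (`N=400`,
`amδ/N ≈ 0.11`) in the test suite.

**Game step.** Payoffs of an `n×n` matrix game `A` are *accumulated* (not
degree-normalised) over all `G_δ(t)` neighbours; isolated nodes hold payoff
0 and skip updating.  Every connected node then picks one neighbour
uniformly at random and adopts its strategy with the Fermi probability
`1/(1+e^{−β(P_v−P_u)})`.  The baseline update is **synchronous** (all
decisions evaluated against the pre-update state); an
asynchronous-random-order sweep is available as a config switch.  At the
weak selection intensities the theory targets the two schemes are
statistically indistinguishable.

**Observables.** Per-strategy activity moments
`I^k_i = (1/N) Σ_{u: s_u=i} a_u^k` (so `I⁰_i = x_i`), recorded every step;
stationary values are time averages over a recording window (default 250
steps) after a relaxation window (default 750 steps), over replicate runs
that resample both strategies and activities (activities can be frozen with
`freeze_activities`).

## Weak-selection theory

Expanding the Fermi function to first order in `β` and closing the moment
hierarchy on its slow manifold `I^k = ⟨a^k⟩ x` yields replicator-like
equations with the transformed matrix `A′ = α₁A + α₂B`, `B = A − Aᵀ`,
`α₁ = β(3mδ⟨a⟩² + mδ⟨a²⟩ − 2⟨a⟩)/2`, `α₂ = β⟨a⟩`.  Only the normalised
weight `ᾱ₂ = α₂/(α₁+α₂) = 2⟨a⟩/(mδ(3⟨a⟩²+⟨a²⟩))` matters for phase
portraits, because a positive rescaling of the payoff matrix only rescales
time (verified as a Hausdorff-distance test on trajectories).  The ESS
condition on the temporal network is `α₁a_ii + α₂a_ij > (α₁+α₂)a_ji` for
all rivals `j`; equality is the ungeneric case and is reported as a
three-valued `undecided` verdict rather than coerced to a boolean.

## Numerical design

* **RNG.** All stochastic components draw from `numpy` Generators split
  deterministically per (seed, replicate, window) via `SeedSequence` spawn
  keys; identical seeds give identical edge sets and trajectories.
* **Snapshot sampling.** Partner draws use a vectorised
  redraw-until-distinct scheme (exact uniform without-replacement
  conditioning); edges are deduplicated via integer pair codes.
* **Simplex integration.** `solve_ivp`/DOP853 with `rtol 1e-11`,
  `atol 1e-13` (tight enough that raw simplex drift stays below `1e-9` over
  `t ~ 10³`); sampled states are clipped at 0 and renormalised, with the
  pre-normalisation drift reported.  Vertex absorption within `1e-6` is
  recorded as an event.  A uniform mutation term `ε(1/n − x_i)` is available
  purely as a stress test for structural stability of boundary attractors.
* **Log-coordinate integration.** For conservation checks along
  trajectories that approach the boundary exponentially, the flow is also
  integrated in `y = ln x` coordinates, where vanishing frequencies keep
  relative accuracy for arbitrarily deep boundary approaches and the
  mini-ultimatum cross-ratio `log K = y_R + y_F − y_G − y_I` is a linear
  invariant (conserved to ~1e-13 over `t = 10³`).
* **Fixed points.** The replicator Jacobian is evaluated in closed form
  (finite-difference cross-checked in tests) and projected onto the
  `(n−1)`-dimensional simplex tangent space.  Eigenvalue real parts beyond
  `±tol` (default `1e-7`) count as unstable/stable; a zero direction with no
  unstable one marks a non-isolated rest point, the situation on the
  generous–fair rest-point line of the mini-ultimatum game.

## The moment hierarchy: truncation vs density route

The selection-free hierarchy
`İ^k = (−I^{k+1} − ⟨a⟩I^k + ⟨a^k⟩I^1 + ⟨a^{k+1}⟩I^0)/2` can be integrated
directly in truncated raw-moment coordinates (`moment_hierarchy_rhs`, with
either a stationarity-relation closure at the top order or a
manifold-value closure).  Both closures leave the slow manifold exactly
invariant, but *truncation in raw-moment coordinates is linearly unstable*
for broad activity densities: for the near-uniform density the closed
linear system acquires spurious positive eigenvalues (~0.1) once
`k_max ≥ 4`, so off-manifold integrations diverge over long horizons.  The
package therefore also integrates the joint density `x_{a,i}` of (activity,
strategy) on a Gauss–Legendre grid (`integrate_activity_density`, default
40 nodes) — the equation one level up, whose moments satisfy the hierarchy
*exactly with no closure*.  This route is uniformly stable: any off-manifold
start relaxes to `I^k = ⟨a^k⟩x` to ~1e-10, and with selection at
`β = 10⁻³` its frequency dynamics matches the transformed-matrix replicator
flow with an error that scales linearly in `β` over a `1/β` horizon (i.e.
`O(β²)` per unit time), halving when `β` halves.

## Known modelling gap in the mean-field selection terms

The four-channel mean-field gain/loss rate weighs a candidate role model
`(a′, j)` for a focal `(a, i)` by the raw contact factor `a + a′`.  The
simulator's actual rule — *pick one neighbour uniformly* — implies an
additional normalisation by the focal's neighbourhood composition
(`a + ⟨a⟩` in expectation).  An enumeration oracle (exact expected one-step
moment change on a frozen graph, validated against Monte-Carlo sweeps)
shows that the annealed drift of the real update differs from the
unnormalised four-channel form by a systematic ~10–15% of the `O(β)` drift
that does not vanish with mean degree.  Both readings share the neutral
dynamics, the slow manifold, and hence all `β → 0` predictions; the
discrepancy rescales the effective selection weights at finite `β` but
cannot flip any sign-based conclusion (ESS verdicts, phase boundaries) that
depends only on `ᾱ₂`-ratios of the same form.  The package implements the
closed-form theory exactly as stated above and flags the residual in the
test suite rather than absorbing it.

## Synthetic-data scope

All experiments are generated in-package; there is no external data.  The
generator reproduces the study conditions used throughout: near-uniform
activity density `f(a) = 1000/999` on `[0.001, 1]`, `m = 4`, `δ = 2`,
`β = 10⁻⁶`, the 2×2 coordination game `[[1,0],[0,0.5]]`, and the
mini-ultimatum parameter sets `(h,l) ∈ {(0.3,0.2), (0.45,0.2),
(0.45,0.42)}` with `(α₁,α₂) = (1,2)`.  The stationary-moment protocol runs
`N = 4000` with 25 replicates per initial mixture (the upper end of the
published range is `N = 10⁴` with 200 initial conditions; the reduced scale
raises sampling error by ~2× and is accounted for by the
standard-error-based agreement bands).  What passing tests show is
agreement between simulator and theory *under activity-driven rewiring with
i.i.d. memoryless activations*; they say nothing about empirical temporal
networks with burstiness, memory, or topological correlations, which are
outside this model class.

## Limitations

* Finite-`N` fluctuations cause extinction/fixation events the
  deterministic theory cannot capture; at `N ≲ 10³` and long horizons the
  moment protocol's agreement degrades accordingly.
* The deterministic theory is `O(β)`-accurate; at `β ≳ 10⁻²` Fermi
  curvature and the neighbour-normalisation gap above both become visible.
* The continuous-strategy ultimatum game (offer/threshold continuum) and
  degree-normalised ("average payoff") update rules are out of scope.
* Point-mass activity distributions have no density route; the moment
  hierarchy is degenerate there (all moments are powers of `a₀` times the
  frequencies) and handled by the closed forms alone.
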