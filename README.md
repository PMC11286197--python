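# temporal-egt

Evolutionary game dynamics on **activity-driven temporal networks**: a
stochastic agent-based simulator coupled to the matching deterministic
weak-selection theory, applied to the evolution of fairness in the
mini-ultimatum game.

Many real interaction networks are temporal: links exist intermittently and
are continually rebuilt.  In the activity-driven model, each of `N`
individuals carries an activity potential `a_u ∈ (0,1]` drawn from a density
`f(a)`; per time step, active individuals wire `m` random links, the union
of `δ` consecutive snapshots forms the interaction graph `G_δ(t)`, payoffs
of an `n×n` pairwise game `A` are accumulated over neighbours, and every
individual imitates a random neighbour with the Fermi probability
`F(ΔP) = 1/(1+e^{−βΔP})`.  This package is for researchers in evolutionary
game theory / theoretical ecology who want either the simulator, the
closed-form theory, or both sides of that comparison.

## The theory in brief

In the weak-selection limit `β → 0` the mean strategy frequencies `x(t)`
obey replicator-like equations with a **transformed payoff matrix**

```
ẋ_i = x_i [ (A′x)_i − x·A′x ],      A′ = α₁ A + α₂ B,      B = A − Aᵀ,
α₁ = β (3mδ⟨a⟩² + mδ⟨a²⟩ − 2⟨a⟩)/2,  α₂ = β ⟨a⟩,
```

where `B` is the antisymmetric *local-competition* (zero-sum) matrix and
`⟨a^k⟩` are the moments of `f`.  Strategy `i` is evolutionarily stable on
the temporal network iff `α₁ a_ii + α₂ a_ij > (α₁+α₂) a_ji` for every rival
`j`.  The per-strategy activity moments `I^k_i` (with `I⁰_i = x_i`)
equilibrate fast onto the slow manifold `I^k_i = ⟨a^k⟩ x_i`, which is what
the simulator's stationary states reproduce.

For the **mini-ultimatum game** (strategies R=[l,l], G=[h,l], F=[h,h],
I=[l,h] with offer levels `0 < l < h < 1/2`), the reasonable strategy R
loses evolutionary stability exactly when `l < α₂/(α₁+2α₂)`, the interior
carries the conserved cross-ratio `K = x_R x_F/(x_G x_I)`, and temporal
population structure stabilises the fair strategy F — fairness emerges from
network temporality alone.

## Worked example

```python
>>> import temporal_egt as te
>>> dist = te.ActivityDistribution.uniform(0.001, 1.0)   # f(a) = 1000/999
>>> w = te.selection_weights(beta=1e-6, m=4, delta=2, dist=dist)
>>> round(w.alpha2_norm, 4)                              # normalised weight of B
0.1153
>>> te.critical_offer(alpha1=1.0, alpha2=2.0)            # R destabilised below this l
0.4
>>> v, rivals = te.ess_temporal(te.mug_matrix(h=0.3, l=0.2), 1.0, 2.0, i=0)
>>> v.value, min(rivals, key=lambda r: r.margin).rival
('not-ESS', 3)
```

With `l = 0.2 < 0.4` the reasonable strategy is invadable, and its binding
rival (index 3) is the immoral strategy — low offers are punished through
local competition.  The same threshold organises the whole phase diagram:

```python
>>> df = te.phase_diagram([2.0], [0.2, 0.42])
>>> list(df.verdict)
['R-unstable', 'R-stable']
```

On the stochastic side, a short stationary-moment run
(`te.run_replicates(...)`, see `tests/test_acceptance.py` for the full
protocol) yields per-strategy moments `I^k` that match `⟨a^k⟩·x` within
sampling error up to `k = 8`.

A CLI wraps the four standard experiments:

```bash
temporal-egt ess   --config ess.yaml   --out runs/ess
temporal-egt phase --config phase.yaml --out runs/phase
temporal-egt ode   --config ode.yaml   --out runs/ode
temporal-egt abm   --config abm.yaml   --out runs/abm
```

each writing CSV/JSON artifacts plus a `manifest.json` that reproduces the
run.  See the `cli` module docstring for the config schema.

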