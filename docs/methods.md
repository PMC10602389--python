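# Methods

## Model and update rule

The simulator advances `N` walkers on an `L × L` lattice in discrete time.
All walkers update **synchronously**: every decision at step `t → t+1` reads
histories up to index `t` only, so a peer's move within the same step is not
yet visible.  Synchrony makes the update a map on time-`t` quantities,
order-independent and exactly reproducible; at the default swarm size
(N = 200) results should be insensitive to the synchronous/sequential choice,
which the update-rule statement leaves open.

Per walker and step:

1. **Feeding.**  On a target of attractiveness `γ`, remain with probability
   `γ`.  Sojourn lengths are geometric with mean `1/(1−γ)` — the site's
   reward.
2. **Otherwise** partition the move as `q(1−ρ)` self-memory, `qρ`
   peer-memory, `1−q` random exploration.
3. **Memory recall** picks `t′ ∈ [0, t]` with probability
   `p_t(t′) ∝ F_t(t′)` and relocates to the recalled site (own history, or
   that of a peer drawn uniformly from the other `N−1`; the peer's history is
   read up to the same index `t`).  Recalling the currently occupied site is
   allowed and counts as reinforcement.
4. **Exploration** adds two independent signed components with
   `P(ℓ) ∝ |ℓ|^−(1+μ)`, `|ℓ| ∈ {1, …, ℓ_max}` (Lévy mode), or a uniform step
   to one of the 4 von-Neumann neighbours (nearest-neighbour mode; the
   diagonal-free neighbourhood is the standard square-lattice choice).
   Results are folded back by the boundary rule.

### Boundaries

Reflective walls sit at −0.5 and `L−0.5`, i.e. coordinates fold with period
`2L` (`r = x mod 2L`; if `r ≥ L` then `2L−1−r`).  This is well defined for
jumps of any magnitude, so the Lévy cutoff is a modelling knob rather than a
numerical necessity.  A periodic option exists because on the torus every
symmetric step law has a doubly stochastic transition matrix, making the
memoryless stationary law *exactly* `P_i ∝ 1/(1−γ_i)` — the analytic oracle
used in the tests.  With reflective walls the law is exact for
nearest-neighbour steps' lazy analogues only up to boundary corrections, so
the oracle comparison is run periodic.

### Lévy cutoff

Default `ℓ_max = 10·L`.  At `μ = 0` the power law is non-normalisable without
a cutoff, so one is mandatory anyway; for `μ ≥ 0.5` the truncated tail mass
beyond `10·L` is negligible and jumps beyond the lattice are folded.  The
cutoff is recorded in run metadata and configurable.

## Memory kernels and the shared lag table

Kernel weights depend only on the lag `t − t′`:
power `(lag+1)^−β` (β ≥ 0; β = 0 reduces to linear preferential visits,
i.e. infinite memory), exponential `e^−(lag+1)/Δ` (the prefactor cancels
under normalisation).  One cumulative lag table per run therefore serves all
walkers at every time: it is extended geometrically as `t` grows and sampled
by inverse CDF with binary search — O(log t) per draw, O(T) memory — instead
of a naive per-walker O(t) scan, which would make `T = 10⁵` horizons
impractical.  β = 0 short-circuits to a uniform integer draw (exact).  The
table is accumulated in double precision; for the β and T ranges used here
the partial sums stay well within range (no under- or overflow).

## Observables

- **Occupation** `P_Ti`: fraction of walker-snapshots on target `i`, by
  default one final-time snapshot per realization, averaged over
  realizations and then over landscapes.  A time-window average over the
  tail of a run is available as a variance-reduction option; in the steady
  state the two estimators agree.
- **Learning curve** `N_Tbest(t)`: fraction of walkers whose first visit to
  the best target is ≤ t; right-continuous, monotone.  The mean first-passage
  time equals `Σ_{t≥0} (1 − N_Tbest(t))`, an identity that is exact on any
  finite sample with all visits observed and is verified rather than assumed;
  walkers that never visit are flagged, never silently truncated.
- **Cohesion** `N_r(t)`: mean number of other walkers within Euclidean
  distance `r`, computed with a k-d-tree pair count every `obs_every` steps
  (default 100 — learning times are far longer than this cadence, and
  per-step O(N²) counting is wasteful).  The radius defaults to
  `r = L/(2√N)`: half the typical nearest-neighbour distance of `N` uniform
  points on the domain (which scales as `L/√N`); an explicit radius override
  is accepted.  A uniform scatter gives the Poisson anchor
  `E[N_r] ≈ πr²(N−1)/L²` used as a sanity check of the pair counting.
- **`N_r∞`**: mean of `N_r(t)` over the final 10% of observations (window
  configurable).  If the last-window linear trend exceeds 5% of the level,
  the estimate carries a non-stationarity warning instead of failing.
- **`τ`**: first observation time at which the trailing moving average
  (window 5 observations, configurable) of `N_r(t)` reaches `N_r∞/2`;
  undefined when cohesion never develops.  The smoothing and window choices
  are this package's own operationalisation; both are exposed.

## Landscapes

`M = round(δL²)` targets exactly — fixing the count (rather than treating δ
as a mean) removes nuisance variance between replicate landscapes; the
reference setting L = 200, δ = 0.0025 gives exactly M = 100.  Sites are
sampled without replacement (one weight per site); weights are i.i.d.
`U(0, γ_max)`.  The best target is the argmax weight, ties broken by lowest
index (probability zero under continuous weights).  A *landscape* is
positions plus weights, both controlled by one environment seed, separate
from the dynamics seed, so "many dynamics in one environment" is
expressible.  Power-law-distributed attractiveness, depleting or refreshing
resources, travel costs and non-complete interaction networks are out of
scope.

## Sweeps and derived estimates

A sweep varies one axis (`rho`, `q`, `beta`, `mu`, `delta_mem`) over a grid,
with `n_environments × n_realizations` runs per point.  Every run seed is a
pure function of (master seed, grid index, environment index, realization
index) via `numpy.random.SeedSequence`, so sweeps are bit-for-bit
reproducible and resumable from a per-run cache keyed by a parameter hash.
Aggregation is mean over realizations within a landscape, then across
landscapes; dispersion is reported across landscapes as both SD and SE
(conventions for published error bars vary, so both are kept).

The localization threshold `q_t` is the linear-interpolated crossing of the
`P_Tbest(q)` curve above a criterion, by default 100× the analytic
memoryless `P_Tbest` of the environment — chosen so pure random walks can
never trigger it; the criterion is configurable because the threshold has no
canonical numeric definition.  Curve optima (`β*`, `q*`) are grid argmaxes
refined by a parabola through the maximum and its neighbours, reported with
one grid spacing as the uncertainty and flagged when the maximum sits on the
grid edge (optimum not bracketed).

## Problem sizes and what the tests show

The reference conditions are L = 200, N = 200, γ_max = 0.9, δ = 0.0025,
T = 10⁵ steps.  The test suite and the acceptance script keep the full
lattice, swarm and horizon but reduce the *averaging*: 4 landscapes ×
5 realizations per condition instead of 10 × 1000.  Under that reduction the
best-target occupation of Lévy swarms at the optimal decay exponent
(β = 1.5) and its fold improvement over infinite memory are reproduced to
within a few hundredths / tens of percent; curve-level sweeps (over ρ, q, β,
μ) at full grid resolution are supported by the sweep machinery but are
hours-scale and not exercised in the default suite.  Unit-level checks
compare against exact results (the memoryless stationary law, hand-normalised
kernel probabilities, zeta-function jump masses, the first-passage area
identity), so they validate the mechanics independently of replicate counts.

The synthetic landscapes are the model's own environment definition, not an
emulation of field data: passing tests demonstrate the collective-learning
phenomenology of the model (selective localization, cohesion growth,
decay-induced speed-up), not agreement with any animal tracking data.

## Numerical and degenerate-input choices

- `q = 1, ρ = 0`: the only history entry is the start site — walkers freeze;
  covered by tests as a limit, not an error.
- `N = 1` with `ρ > 0`: peer mode is impossible; treated as `ρ = 0` with a
  warning.
- `t = 0` recall is the single admissible time 0.
- All-never first-visit samples give an undefined MFPT with the
  never-fraction reported.
- One RNG stream per run (`numpy` PCG64), seeded; environment and dynamics
  seeds independent.
- History is a dense `(T+1) × N` int32 array (~80 MB at the reference
  scale): O(1) site lookup after a lag draw.

## Known limitations

- Complete interaction network only; no competition, depletion or patch
  refresh; static landscapes.
- `N_r∞` and `τ` depend mildly on the estimator windows when a run is
  stopped before the cohesion plateau; the non-stationarity warning flags
  that case rather than correcting it.
- Reduced replicate counts leave landscape-to-landscape variability visible
  in headline numbers at the few-hundredths level.
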