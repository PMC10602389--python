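# levyswarm

Agent-based simulation of collective foraging by interacting walkers that
combine **Lévy-flight exploration**, **decaying spatial memory** and **social
information transfer** on a heterogeneous resource landscape.  The package is
aimed at movement ecologists and collective-behaviour modellers who want a
fast, reproducible implementation of this family of reinforced-walk swarm
models, together with the observables used to quantify collective learning.

## The model

`N` walkers move on an `L × L` lattice holding `M = round(δL²)` resource
targets; target `i` has attractiveness `γ_i ~ U(0, γ_max)`, the per-step
probability of continuing to feed there (mean visit length `1/(1−γ_i)`).
Each step, a walker off a target:

- with probability `q(1−ρ)` relocates to a site from **its own history**,
  picking a past time `t′ ∈ [0, t]` with probability
  `p_t(t′) = F_t(t′)/C(t)` — frequently and recently visited sites are
  preferentially revisited;
- with probability `qρ` does the same using the history of a **uniformly
  chosen peer** (information transfer on a complete network);
- with probability `1−q` takes a **random exploratory step**: two independent
  signed components from the power law `p(ℓ) ∝ |ℓ|^−(1+μ)` (Lévy flights,
  `0 ≤ μ ≤ 2`), or a nearest-neighbour step.

The memory kernel is `F_t(t′) = (t−t′+1)^−β` (power-law decay; `β = 0` is the
non-decaying linear preferential-visit limit) or
`F_t(t′) ∝ e^−(t−t′+1)/Δ` (exponential).

Observables: per-target occupation probabilities `P_Ti` (selective
localization, with `P_Tbest` for the most attractive site), the learning
curve `N_Tbest(t)` and the mean first-passage time to the best site (equal to
the area between the curve and 1), group cohesion `N_r(t)` within radius
`r = L/(2√N)`, its steady state `N_r∞`, and the learning time `τ` (first time
cohesion reaches half of `N_r∞`).  For memoryless walkers (`q = 0`) the exact
stationary occupation `P_i = C(L)/(1−γ_i)` serves as a built-in correctness
oracle.

## Worked example

```python
from levyswarm import (KernelSpec, SimConfig, generate_environment, run,
                       target_occupation)

env = generate_environment(L=200, delta=0.0025, gamma_max=0.9, seed=1)
cfg = SimConfig(N=200, q=0.25, rho=0.5, movement="levy", mu=0.5,
                kernel=KernelSpec(family="power", beta=1.5),
                T=10_000, seed=2)
res = run(env, cfg)
occ = target_occupation(res.final_sites, env)
print(f"targets: {env.n_targets}  gamma_best: {env.gamma_best:.3f}")
print(f"P_Tbest: {occ.p_best:.3f}  cohesion tail: {res.n_r[-1]:.1f}")
```

prints (one realization in one landscape):

```
targets: 100  gamma_best: 0.899
P_Tbest: 0.505  cohesion tail: 62.5
```

Half the 200 walkers sit on the single best of 40,000 lattice sites after
10⁴ steps — selective localization — and a walker has on average ~60 group
members within `r ≈ 7.1` lattice units.  The same run with `q=0` gives
`P_Tbest ~ 2.5e-4` (the memoryless baseline `C(L)/(1−γ_best)`).

The same machinery is scriptable from the shell:

```sh
levyswarm env-gen -L 200 --delta 0.0025 --seed 1 --out env.json
levyswarm simulate --config cfg.yaml --env env.json --out out/
levyswarm sweep --spec sweep.yaml --out sweepdir/
levyswarm plot --aggregated sweepdir/aggregated.csv --out panels.png
```

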