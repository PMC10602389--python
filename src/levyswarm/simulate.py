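"""The N-walker foraging dynamics.

Each discrete time step ``t -> t+1`` every walker updates synchronously from
the histories available at time ``t``:

* on a target of weight ``gamma``: keep feeding with probability ``gamma``,
  otherwise leave via one of the movement modes below;
* off a target (or leaving): with probability ``q(1-rho)`` jump to one of its
  own previously occupied sites, chosen by the kernel-weighted preferential
  recall rule; with probability ``q*rho`` do the same using the history of a
  uniformly chosen peer (information transfer); with probability ``1-q`` take
  a random exploratory step.

Exploration is either a Lévy flight — two i.i.d. signed components drawn from
``p(l) ∝ |l|^(-(1+mu))`` — or a nearest-neighbour (von Neumann) step.  Steps
are folded back into the lattice by reflective (default) or periodic
boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .environment import Environment
from .kernels import KernelSpec, RecallSampler

__all__ = [
    "SimConfig",
    "SwarmState",
    "TrajectorySet",
    "SimResult",
    "LevyStepSampler",
    "sample_levy_component",
    "apply_boundary",
    "choose_move_mode",
    "init_state",
    "step",
    "run",
]

NEVER = -1  # sentinel first-visit time for walkers that never reach the best site


@dataclass(frozen=True)
class SimConfig:
    """All dynamics parameters of a run.

    Parameters
    ----------
    N : int
        Number of walkers (complete communication network).
    q : float
        Probability of using memory on an off-target move.
    rho : float
        Probability that a memory move uses a peer's history instead of own.
    movement : {"levy", "nn"}
        Exploration mode: power-law jumps or nearest-neighbour steps.
    mu : float
        Lévy index in [0, 2]; tail exponent of the jump law (ignored in
        ``nn`` mode).
    kernel : KernelSpec
        Memory-decay kernel for preferential recall.
    T : int
        Horizon (number of steps).
    boundary : {"reflective", "periodic"}
    obs_every : int
        Cadence (steps) of cohesion/learning-curve observations.
    seed : int
        Dynamics RNG seed (independent of the environment seed).
    levy_cutoff : int or None
        Maximum jump magnitude; defaults to ``10 * L`` at run time.  A finite
        cutoff is mandatory at ``mu = 0`` where the jump law is otherwise
        non-normalisable.
    """

    N: int = 200
    q: float = 0.25
    rho: float = 0.5
    movement: str = "levy"
    mu: float = 0.5
    kernel: KernelSpec = field(default_factory=KernelSpec)
    T: int = 100_000
    boundary: str = "reflective"
    obs_every: int = 100
    seed: int = 0
    levy_cutoff: int | None = None

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"need N >= 1 walkers, got {self.N}")
        if not (0.0 <= self.q <= 1.0):
            raise ValueError(f"q must lie in [0, 1], got {self.q}")
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError(f"rho must lie in [0, 1], got {self.rho}")
        if self.movement not in ("levy", "nn"):
            raise ValueError(f"movement must be 'levy' or 'nn', got {self.movement!r}")
        if self.movement == "levy" and not (0.0 <= self.mu <= 2.0):
            raise ValueError(f"Levy index mu must lie in [0, 2], got {self.mu}")
        if self.T < 1:
            raise ValueError(f"horizon T must be >= 1, got {self.T}")
        if self.boundary not in ("reflective", "periodic"):
            raise ValueError(f"boundary must be 'reflective' or 'periodic', got {self.boundary!r}")
        if self.obs_every < 1:
            raise ValueError(f"obs_every must be >= 1, got {self.obs_every}")
        if self.levy_cutoff is not None and self.levy_cutoff < 1:
            raise ValueError(f"levy_cutoff must be >= 1, got {self.levy_cutoff}")


def sample_levy_component(
    mu: float,
    cutoff: int,
    rng: np.random.Generator,
    size: int | None = None,
):
    """Signed non-zero jump component(s) with ``P(l) ∝ |l|^(-(1+mu))`` on ±1..±cutoff."""
    sampler = LevyStepSampler(mu, cutoff)
    out = sampler.sample(1 if size is None else size, rng)
    return int(out[0]) if size is None else out


class LevyStepSampler:
    """Inverse-CDF table sampler for the truncated power-law jump magnitude."""

    def __init__(self, mu: float, cutoff: int):
        if not (0.0 <= mu <= 2.0):
            raise ValueError(f"mu must lie in [0, 2], got {mu}")
        if cutoff < 1:
            raise ValueError(f"cutoff must be >= 1, got {cutoff}")
        self.mu = mu
        self.cutoff = cutoff
        mags = np.arange(1, cutoff + 1, dtype=np.float64)
        w = mags ** (-(1.0 + mu))
        self._cum = np.cumsum(w)

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        u = rng.random(size) * self._cum[-1]
        mag = 1 + np.searchsorted(self._cum, u, side="right")
        sign = np.where(rng.random(size) < 0.5, -1, 1)
        return sign * mag


def apply_boundary(x, L: int, mode: str = "reflective"):
    """Fold an (array of) integer coordinate(s) back into ``[0, L-1]``.

    Reflective walls sit at -0.5 and L-0.5, giving a fold of period ``2L``;
    periodic is a plain modulus.  Idempotent on in-range coordinates.
    """
    x = np.asarray(x)
    if mode == "periodic":
        out = np.mod(x, L)
    elif mode == "reflective":
        r = np.mod(x, 2 * L)
        out = np.where(r >= L, 2 * L - 1 - r, r)
    else:
        raise ValueError(f"unknown boundary mode {mode!r}")
    return int(out) if out.ndim == 0 else out.astype(np.int64)


def choose_move_mode(
    on_target: bool,
    gamma: float,
    q: float,
    rho: float,
    rng: np.random.Generator,
) -> str:
    """Draw one move decision for a single walker.

    Returns one of ``stay_feeding``, ``self_memory``, ``peer_memory``,
    ``random_step``.  A walker on a target keeps feeding with probability
    ``gamma``; otherwise (and always off-target) the off-target partition
    ``q(1-rho) + q*rho + (1-q)`` applies.
    """
    if on_target and rng.random() < gamma:
        return "stay_feeding"
    u = rng.random()
    if u < q * (1.0 - rho):
        return "self_memory"
    if u < q:
        return "peer_memory"
    return "random_step"


@dataclass
class SwarmState:
    """Mutable state advanced by :func:`step`.

    ``history[k, l]`` is the flat site index (``x*L + y``) of walker ``l`` at
    time ``k``; rows ``0..t`` are valid.  Dense storage keeps memory recall an
    O(1) lookup after the lag draw.
    """

    t: int
    L: int
    history: np.ndarray            # (T+1, N) int32 flat site indices
    first_visit_best: np.ndarray   # (N,) int64, NEVER if not yet visited

    @property
    def positions(self) -> np.ndarray:
        """Current (N, 2) coordinates."""
        s = self.history[self.t]
        return np.stack([s // self.L, s % self.L], axis=1)


@dataclass(frozen=True)
class TrajectorySet:
    """Full per-walker position history of a run plus best-site first visits."""

    L: int
    sites: np.ndarray              # (T+1, N) flat site indices
    first_visit_best: np.ndarray   # (N,) int64, NEVER where unvisited

    @property
    def n_walkers(self) -> int:
        return self.sites.shape[1]

    @property
    def T(self) -> int:
        return self.sites.shape[0] - 1

    def coordinates(self, t: int) -> np.ndarray:
        """(N, 2) walker coordinates at time ``t``."""
        s = self.sites[t]
        return np.stack([s // self.L, s % self.L], axis=1)


@dataclass(frozen=True)
class SimResult:
    """Run output: observables series, final snapshot, optional trajectory."""

    config: SimConfig
    env_seed: int
    obs_times: np.ndarray          # observation instants (steps)
    n_r: np.ndarray                # cohesion N_r(t) at obs_times
    n_best: np.ndarray             # fraction having visited the best site by t
    first_visit_best: np.ndarray
    final_sites: np.ndarray        # (N,) flat site indices at t = T
    radius: float
    trajectory: TrajectorySet | None = None


class _StepWork:
    """Per-run samplers and lattice tables reused across steps."""

    def __init__(self, env: Environment, cfg: SimConfig):
        self.L = env.L
        self.gamma_flat = env.gamma_flat()
        self.best_site = env.best_site_flat()
        self.recall = RecallSampler(cfg.kernel, capacity=min(cfg.T + 1, 1 << 16))
        cutoff = cfg.levy_cutoff if cfg.levy_cutoff is not None else 10 * env.L
        self.levy = LevyStepSampler(cfg.mu, cutoff) if cfg.movement == "levy" else None
        rho = cfg.rho
        if cfg.N == 1 and rho > 0.0:
            warnings.warn(
                "single walker cannot use peer memory; treating rho as 0",
                stacklevel=3,
            )
            rho = 0.0
        self.q = cfg.q
        self.rho = rho
        self.movement = cfg.movement
        self.boundary = cfg.boundary


def init_state(env: Environment, cfg: SimConfig, rng: np.random.Generator) -> SwarmState:
    """Place walkers uniformly at random and allocate the history buffer."""
    sites0 = rng.integers(0, env.L * env.L, size=cfg.N)
    history = np.empty((cfg.T + 1, cfg.N), dtype=np.int32)
    history[0] = sites0
    first = np.full(cfg.N, NEVER, dtype=np.int64)
    first[sites0 == env.best_site_flat()] = 0
    return SwarmState(t=0, L=env.L, history=history, first_visit_best=first)


def step(
    state: SwarmState,
    env: Environment,
    cfg: SimConfig,
    rng: np.random.Generator,
    _work: _StepWork | None = None,
) -> SwarmState:
    """Advance the swarm one step (synchronous update), in place.

    All walkers read histories up to index ``t`` only; a peer's move within
    the same step is not yet visible.
    """
    work = _work if _work is not None else _StepWork(env, cfg)
    t = state.t
    L = work.L
    N = state.history.shape[1]
    site = state.history[t]

    gamma_here = work.gamma_flat[site]
    u_stay = rng.random(N)
    moving = u_stay >= gamma_here  # off-target sites have gamma 0: always move

    u_mode = rng.random(N)
    q, rho = work.q, work.rho
    self_m = moving & (u_mode < q * (1.0 - rho))
    peer_m = moving & (u_mode >= q * (1.0 - rho)) & (u_mode < q)
    rand_m = moving & (u_mode >= q)

    new_site = site.copy()

    mem_idx = np.flatnonzero(self_m | peer_m)
    if mem_idx.size:
        tprime = work.recall.sample(t, mem_idx.size, rng)
        owner = mem_idx.copy()
        is_peer = peer_m[mem_idx]
        n_peer = int(is_peer.sum())
        if n_peer:
            me = mem_idx[is_peer]
            other = rng.integers(0, N - 1, size=n_peer)
            other[other >= me] += 1  # uniform over the N-1 other walkers
            owner[is_peer] = other
        new_site[mem_idx] = state.history[tprime, owner]

    r_idx = np.flatnonzero(rand_m)
    if r_idx.size:
        x, y = site[r_idx] // L, site[r_idx] % L
        if work.movement == "levy":
            nx = x + work.levy.sample(r_idx.size, rng)
            ny = y + work.levy.sample(r_idx.size, rng)
        else:
            d = rng.integers(0, 4, size=r_idx.size)
            nx = x + np.where(d == 0, 1, 0) - np.where(d == 1, 1, 0)
            ny = y + np.where(d == 2, 1, 0) - np.where(d == 3, 1, 0)
        nx = apply_boundary(nx, L, work.boundary)
        ny = apply_boundary(ny, L, work.boundary)
        new_site[r_idx] = nx * L + ny

    state.history[t + 1] = new_site
    newly = (new_site == work.best_site) & (state.first_visit_best == NEVER)
    state.first_visit_best[newly] = t + 1
    state.t = t + 1
    return state


def run(
    env: Environment,
    cfg: SimConfig,
    record_trajectory: bool = False,
) -> SimResult:
    """Execute ``T`` steps and stream the observables.

    Cohesion ``N_r(t)`` and the learning curve are recorded every
    ``cfg.obs_every`` steps (and at ``t = 0`` and ``t = T``).  Identical
    (environment seed, dynamics seed) pairs give bitwise-identical output.
    """
    from .observables import cohesion, neighborhood_radius

    rng = np.random.default_rng(cfg.seed)
    work = _StepWork(env, cfg)
    state = init_state(env, cfg, rng)

    r = neighborhood_radius(env.L, cfg.N)
    obs_times = [0]
    n_r = [cohesion(state.positions, r)]
    n_best = [float(np.mean(state.first_visit_best == 0))]

    for t in range(cfg.T):
        step(state, env, cfg, rng, _work=work)
        now = state.t
        if now % cfg.obs_every == 0 or now == cfg.T:
            obs_times.append(now)
            n_r.append(cohesion(state.positions, r))
            fv = state.first_visit_best
            n_best.append(float(np.mean((fv != NEVER) & (fv <= now))))

    traj = None
    if record_trajectory:
        traj = TrajectorySet(
            L=env.L,
            sites=state.history.copy(),
            first_visit_best=state.first_visit_best.copy(),
        )
    return SimResult(
        config=cfg,
        env_seed=env.seed,
        obs_times=np.array(obs_times, dtype=np.int64),
        n_r=np.array(n_r),
        n_best=np.array(n_best),
        first_visit_best=state.first_visit_best.copy(),
        final_sites=state.history[cfg.T].astype(np.int64),
        radius=r,
        trajectory=traj,
    )
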