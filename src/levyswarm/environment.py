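"""Static heterogeneous foraging landscapes.

The environment is an ``L x L`` square lattice on which ``M = round(delta * L**2)``
point resources ("targets") are scattered at distinct, uniformly chosen sites.
Each target ``i`` carries a fixed attractiveness ``gamma_i`` drawn i.i.d. from
``Uniform(0, gamma_max)``: the per-step probability that a forager standing on
the target keeps feeding there, so the mean visit duration (the site's reward)
is ``1 / (1 - gamma_i)``.  The target with the largest weight is the *best*
target, the site the swarm should collectively learn to exploit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "Target",
    "Environment",
    "generate_environment",
    "best_target",
    "save_environment",
    "load_environment",
]


@dataclass(frozen=True)
class Target:
    """A resource site: lattice coordinates plus attractiveness weight."""

    x: int
    y: int
    gamma: float

    @property
    def site(self) -> tuple[int, int]:
        return (self.x, self.y)


@dataclass(frozen=True)
class Environment:
    """An immutable landscape: lattice size plus the target list.

    Parameters
    ----------
    L : int
        Lattice side length (sites); coordinates run over ``0 .. L-1``.
    density : float
        Target density ``delta``; the number of targets is ``round(delta * L**2)``.
    gamma_max : float
        Upper bound of the uniform attractiveness distribution, ``< 1``.
    seed : int
        Seed of the RNG stream that produced the landscape.
    targets : tuple of Target
        The resource sites, in generation order.
    """

    L: int
    density: float
    gamma_max: float
    seed: int
    targets: tuple[Target, ...]

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ValueError(f"lattice side L must be >= 2, got {self.L}")
        if not (0.0 < self.gamma_max < 1.0):
            raise ValueError(f"gamma_max must lie in (0, 1), got {self.gamma_max}")
        if len(self.targets) < 1:
            raise ValueError("environment must contain at least one target")
        sites = {(t.x, t.y) for t in self.targets}
        if len(sites) != len(self.targets):
            raise ValueError("target sites must be pairwise distinct")
        for t in self.targets:
            if not (0 <= t.x < self.L and 0 <= t.y < self.L):
                raise ValueError(f"target site {t.site} outside lattice of side {self.L}")
            if not (0.0 < t.gamma < 1.0):
                raise ValueError(f"target weight must lie in (0, 1), got {t.gamma}")

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    @property
    def best_index(self) -> int:
        """Index of the best target; ties broken by lowest index."""
        gammas = np.array([t.gamma for t in self.targets])
        return int(np.argmax(gammas))

    @property
    def gamma_best(self) -> float:
        return self.targets[self.best_index].gamma

    def target_sites(self) -> np.ndarray:
        """(M, 2) integer array of target coordinates."""
        return np.array([[t.x, t.y] for t in self.targets], dtype=np.int64)

    def target_weights(self) -> np.ndarray:
        return np.array([t.gamma for t in self.targets], dtype=np.float64)

    def gamma_flat(self) -> np.ndarray:
        """Length ``L*L`` vector of site weights (0 on non-target sites).

        Site ``(x, y)`` maps to flat index ``x * L + y``.
        """
        g = np.zeros(self.L * self.L, dtype=np.float64)
        for t in self.targets:
            g[t.x * self.L + t.y] = t.gamma
        return g

    def best_site_flat(self) -> int:
        b = self.targets[self.best_index]
        return b.x * self.L + b.y


def generate_environment(
    L: int, delta: float, gamma_max: float, seed: int
) -> Environment:
    """Draw a random landscape with ``round(delta * L**2)`` targets.

    Target sites are sampled without replacement (each site holds at most one
    target); weights are i.i.d. ``Uniform(0, gamma_max)``.  The same seed
    always reproduces the same landscape.
    """
    if L < 2:
        raise ValueError(f"lattice side L must be >= 2, got {L}")
    if not (0.0 < delta < 1.0):
        raise ValueError(f"density delta must lie in (0, 1), got {delta}")
    if not (0.0 < gamma_max < 1.0):
        raise ValueError(f"gamma_max must lie in (0, 1), got {gamma_max}")
    M = round(delta * L * L)
    if M < 1:
        raise ValueError(
            f"delta * L**2 = {delta * L * L:.3g} rounds to zero targets; "
            "increase delta or L"
        )
    rng = np.random.default_rng(seed)
    flat = rng.choice(L * L, size=M, replace=False)
    # resample any exact-zero weight (probability zero in theory, the open
    # interval (0, gamma_max) is part of the contract)
    gammas = rng.uniform(0.0, gamma_max, size=M)
    while np.any(gammas == 0.0):  # pragma: no cover
        gammas[gammas == 0.0] = rng.uniform(0.0, gamma_max, size=int(np.sum(gammas == 0.0)))
    targets = tuple(
        Target(x=int(s // L), y=int(s % L), gamma=float(g))
        for s, g in zip(flat, gammas)
    )
    return Environment(L=L, density=delta, gamma_max=gamma_max, seed=seed, targets=targets)


def best_target(env: Environment) -> Target:
    """The target of maximal weight (lowest index wins ties)."""
    return env.targets[env.best_index]


def save_environment(env: Environment, path: str | Path) -> None:
    """Write the landscape as JSON: {L, density, gamma_max, seed, targets}."""
    payload = {
        "L": env.L,
        "density": env.density,
        "gamma_max": env.gamma_max,
        "seed": env.seed,
        "targets": [{"x": t.x, "y": t.y, "gamma": t.gamma} for t in env.targets],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_environment(path: str | Path) -> Environment:
    """Read a landscape written by :func:`save_environment`, re-validating invariants."""
    payload = json.loads(Path(path).read_text())
    targets = tuple(
        Target(x=int(t["x"]), y=int(t["y"]), gamma=float(t["gamma"]))
        for t in payload["targets"]
    )
    return Environment(
        L=int(payload["L"]),
        density=float(payload["density"]),
        gamma_max=float(payload["gamma_max"]),
        seed=int(payload["seed"]),
        targets=targets,
    )
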