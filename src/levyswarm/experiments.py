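"""Declarative parameter sweeps and curve summaries.

A sweep runs ``len(grid) x n_environments x n_realizations`` independent
simulations, varying one axis (``rho``, ``q``, ``beta``, ``mu`` or
``delta_mem``) of a base configuration.  Every run's seed is a pure function
of (master seed, grid index, environment index, realization index), so a
sweep is reproducible bit for bit and resumable.  Aggregation follows the
convention of averaging over realizations within an environment first, then
across environments (dispersion is reported across environments, as both SD
and SE).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .environment import Environment, generate_environment
from .kernels import KernelSpec
from .simulate import SimConfig, run
from .observables import (
    asymptotic_cohesion,
    learning_time,
    mean_first_passage,
    target_occupation,
)

__all__ = [
    "SweepSpec",
    "SweepResult",
    "OptimumEstimate",
    "run_sweep",
    "estimate_threshold",
    "estimate_optimum",
]

_AXES = ("rho", "q", "beta", "mu", "delta_mem")


@dataclass(frozen=True)
class SweepSpec:
    """One-axis scan of the model around a base configuration."""

    base: SimConfig
    axis: str
    grid: tuple[float, ...]
    L: int = 200
    delta: float = 0.0025
    gamma_max: float = 0.9
    n_environments: int = 3
    n_realizations: int = 10
    master_seed: int = 0
    max_runs: int = 20_000

    def __post_init__(self) -> None:
        if self.axis not in _AXES:
            raise ValueError(f"axis must be one of {_AXES}, got {self.axis!r}")
        if len(self.grid) == 0:
            raise ValueError("grid must be non-empty")
        if self.n_environments < 1 or self.n_realizations < 1:
            raise ValueError("need at least one environment and one realization")

    @property
    def n_runs(self) -> int:
        return len(self.grid) * self.n_environments * self.n_realizations


@dataclass(frozen=True)
class SweepResult:
    """Tidy per-run rows plus the across-environment aggregation."""

    spec: SweepSpec
    runs: pd.DataFrame       # one row per (value, environment, realization)
    aggregated: pd.DataFrame  # one row per grid value


def _derive_env_seed(master: int, env_idx: int) -> int:
    ss = np.random.SeedSequence([master, 0x5EED, env_idx])
    return int(ss.generate_state(1)[0] % (2**31))


def _derive_run_seed(master: int, grid_idx: int, env_idx: int, real_idx: int) -> int:
    ss = np.random.SeedSequence([master, grid_idx, env_idx, real_idx])
    return int(ss.generate_state(1)[0] % (2**31))


def _config_at(base: SimConfig, axis: str, value: float, seed: int) -> SimConfig:
    if axis == "beta":
        return replace(base, kernel=KernelSpec(family="power", beta=float(value)), seed=seed)
    if axis == "delta_mem":
        return replace(
            base, kernel=KernelSpec(family="exponential", delta_mem=float(value)), seed=seed
        )
    return replace(base, **{axis: float(value)}, seed=seed)


def _run_key(spec: SweepSpec, value: float, env_seed: int, run_seed: int) -> str:
    ident = json.dumps(
        {
            "axis": spec.axis,
            "value": value,
            "env_seed": env_seed,
            "run_seed": run_seed,
            "L": spec.L,
            "delta": spec.delta,
            "gamma_max": spec.gamma_max,
            "base": repr(spec.base),
        },
        sort_keys=True,
    )
    return hashlib.sha1(ident.encode()).hexdigest()[:16]


def _summarize_run(env: Environment, cfg: SimConfig) -> dict:
    res = run(env, cfg)
    occ = target_occupation(res.final_sites, env)
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        n_r_inf = asymptotic_cohesion(res.n_r)
        tau = learning_time(res.obs_times, res.n_r, n_r_inf)
        mfpt = mean_first_passage(res.first_visit_best)
    return {
        "p_best": occ.p_best,
        "n_r_inf": n_r_inf,
        "tau": np.nan if tau is None else tau,
        "mfpt": mfpt.mean,
        "fraction_never": mfpt.fraction_never,
    }


def run_sweep(spec: SweepSpec, cache_dir: str | Path | None = None) -> SweepResult:
    """Execute the sweep; optionally cache per-run summaries for resumption.

    Raises ``RuntimeError`` with a run-count estimate when the spec exceeds
    its ``max_runs`` budget.  With ``cache_dir`` set, completed runs (keyed by
    a hash of their exact parameters) are skipped on re-execution.
    """
    if spec.n_runs > spec.max_runs:
        raise RuntimeError(
            f"sweep would launch {spec.n_runs} runs, over the budget of "
            f"{spec.max_runs}; shrink the grid or replicate counts"
        )
    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)

    envs = {}
    rows = []
    for ei in range(spec.n_environments):
        env_seed = _derive_env_seed(spec.master_seed, ei)
        envs[ei] = generate_environment(spec.L, spec.delta, spec.gamma_max, env_seed)
    for gi, value in enumerate(spec.grid):
        for ei in range(spec.n_environments):
            env = envs[ei]
            for ri in range(spec.n_realizations):
                run_seed = _derive_run_seed(spec.master_seed, gi, ei, ri)
                key = _run_key(spec, value, env.seed, run_seed)
                summary = None
                if cache is not None and (cache / f"{key}.json").exists():
                    summary = json.loads((cache / f"{key}.json").read_text())
                if summary is None:
                    cfg = _config_at(spec.base, spec.axis, value, run_seed)
                    summary = _summarize_run(env, cfg)
                    if cache is not None:
                        (cache / f"{key}.json").write_text(json.dumps(summary))
                rows.append(
                    {
                        "value": value,
                        "environment": ei,
                        "realization": ri,
                        "env_seed": env.seed,
                        "run_seed": run_seed,
                        "run_key": key,
                        **summary,
                    }
                )
    runs = pd.DataFrame(rows)
    per_env = runs.groupby(["value", "environment"], as_index=False)[
        ["p_best", "n_r_inf", "tau", "mfpt", "fraction_never"]
    ].mean()
    agg = per_env.groupby("value").agg(
        p_best=("p_best", "mean"),
        p_best_sd=("p_best", "std"),
        n_r_inf=("n_r_inf", "mean"),
        n_r_inf_sd=("n_r_inf", "std"),
        tau=("tau", "mean"),
        tau_sd=("tau", "std"),
        mfpt=("mfpt", "mean"),
        fraction_never=("fraction_never", "mean"),
        n_environments=("environment", "nunique"),
    )
    for col in ("p_best", "n_r_inf", "tau"):
        agg[f"{col}_se"] = agg[f"{col}_sd"] / np.sqrt(agg["n_environments"])
    agg = agg.reset_index()
    return SweepResult(spec=spec, runs=runs, aggregated=agg)


def estimate_threshold(
    grid: np.ndarray,
    p_best: np.ndarray,
    criterion: float,
) -> float | None:
    """Linear-interpolated crossing of a localization curve above ``criterion``.

    Returns the smallest axis value at which the curve reaches the criterion,
    or ``None`` when it never does.  ``criterion`` should be far above the
    memoryless baseline (e.g. 100x the analytic best-target occupation) so
    that pure random walks can never trigger it.
    """
    grid = np.asarray(grid, dtype=np.float64)
    curve = np.asarray(p_best, dtype=np.float64)
    if grid.shape != curve.shape:
        raise ValueError("grid and curve must have matching shapes")
    above = np.flatnonzero(curve >= criterion)
    if above.size == 0:
        return None
    i = int(above[0])
    if i == 0:
        return float(grid[0])
    x0, x1 = grid[i - 1], grid[i]
    y0, y1 = curve[i - 1], curve[i]
    return float(x0 + (criterion - y0) / (y1 - y0) * (x1 - x0))


@dataclass(frozen=True)
class OptimumEstimate:
    """Location of a curve maximum, refined by quadratic interpolation."""

    value: float       # refined argmax
    peak: float        # curve value at the sampled argmax
    uncertainty: float  # one grid spacing
    at_edge: bool      # True when the maximum sits on the grid boundary


def estimate_optimum(grid: np.ndarray, curve: np.ndarray) -> OptimumEstimate:
    """Argmax of an aggregated curve with parabolic vertex refinement."""
    grid = np.asarray(grid, dtype=np.float64)
    curve = np.asarray(curve, dtype=np.float64)
    if grid.shape != curve.shape:
        raise ValueError("grid and curve must have matching shapes")
    if grid.size < 5:
        raise ValueError(f"need >= 5 grid points to locate an optimum, got {grid.size}")
    i = int(np.argmax(curve))
    spacing = float(np.max(np.diff(np.sort(grid))))
    if i == 0 or i == grid.size - 1:
        return OptimumEstimate(
            value=float(grid[i]), peak=float(curve[i]), uncertainty=spacing, at_edge=True
        )
    x = grid[i - 1 : i + 2]
    y = curve[i - 1 : i + 2]
    a, b, _ = np.polyfit(x, y, 2)
    vertex = float(grid[i]) if a == 0 else float(-b / (2 * a))
    # keep the refinement inside the bracketing interval
    vertex = float(np.clip(vertex, x[0], x[2]))
    return OptimumEstimate(
        value=vertex, peak=float(curve[i]), uncertainty=spacing, at_edge=False
    )
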