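"""Summary statistics of collective foraging runs.

Covers the steady-state target occupation probabilities (selective
localization), the learning curve and its mean-first-passage-time identity,
group cohesion and the learning time, plus the exact memoryless baseline

    P_i(RW) = C(L) / (1 - gamma_i),    C(L) = 1 / sum_j (1 - gamma_j)^(-1)

(the stationary occupation of independent random walkers with sticky
targets, independent of the step distribution) used as a correctness oracle
for the ``q = 0`` limit of the simulator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .environment import Environment

__all__ = [
    "OccupationStats",
    "MFPTResult",
    "target_occupation",
    "analytic_rw_occupation",
    "learning_curve",
    "mean_first_passage",
    "neighborhood_radius",
    "cohesion",
    "asymptotic_cohesion",
    "learning_time",
]

NEVER = -1


@dataclass(frozen=True)
class OccupationStats:
    """Per-target occupation probabilities and the best-target value."""

    p_target: np.ndarray  # (M,) aligned with env.targets
    p_best: float
    n_snapshots: int
    n_walkers: int


def target_occupation(final_sites: np.ndarray, env: Environment) -> OccupationStats:
    """Fraction of walker-snapshots found on each target.

    Parameters
    ----------
    final_sites : array, shape (R, N) or (N,)
        Flat site indices (``x*L + y``) of the N walkers in each of R
        independent realization snapshots.
    """
    sites = np.atleast_2d(np.asarray(final_sites))
    if sites.size == 0:
        raise ValueError("need at least one snapshot of walker positions")
    R, N = sites.shape
    counts = np.bincount(sites.ravel(), minlength=env.L * env.L)
    tflat = env.target_sites()[:, 0] * env.L + env.target_sites()[:, 1]
    p = counts[tflat] / (R * N)
    return OccupationStats(
        p_target=p,
        p_best=float(p[env.best_index]),
        n_snapshots=R,
        n_walkers=N,
    )


def analytic_rw_occupation(env: Environment) -> np.ndarray:
    """Exact stationary site occupation of memoryless walkers (length L*L).

    Valid for any symmetric step law on the periodic lattice: the walk's
    transition matrix is doubly stochastic, so stickiness alone biases the
    stationary law, giving occupation proportional to ``1/(1 - gamma_i)``
    (``gamma_i = 0`` off targets).
    """
    g = env.gamma_flat()
    w = 1.0 / (1.0 - g)
    return w / w.sum()


def learning_curve(
    first_visit_best: np.ndarray,
    n_walkers: int,
    times: np.ndarray,
) -> np.ndarray:
    """Fraction of walkers having visited the best site at least once by each time.

    ``first_visit_best`` holds per-walker first-visit steps, ``NEVER`` (-1)
    for walkers that never arrived.  Right-continuous step function, monotone
    non-decreasing.
    """
    fv = np.asarray(first_visit_best)
    times = np.asarray(times)
    visited = fv[fv != NEVER]
    return np.searchsorted(np.sort(visited), times, side="right") / n_walkers


@dataclass(frozen=True)
class MFPTResult:
    """Mean first-passage time to the best target plus the tail-sum identity.

    For a finite sample with all first visits observed, the mean equals the
    area between the learning curve and 1:  E[T] = sum_{t>=0} P(T > t).
    ``mean`` is NaN when some walkers never visited (``fraction_never > 0``).
    """

    mean: float
    area: float
    fraction_never: float

    @property
    def defined(self) -> bool:
        return self.fraction_never == 0.0


def mean_first_passage(first_visit_best: np.ndarray) -> MFPTResult:
    """Arithmetic-mean first passage time and its discrete area identity."""
    fv = np.asarray(first_visit_best)
    if fv.size == 0:
        raise ValueError("need at least one walker")
    never = fv == NEVER
    frac_never = float(np.mean(never))
    finite = fv[~never]
    if finite.size == 0:
        return MFPTResult(mean=np.nan, area=np.nan, fraction_never=frac_never)
    # tail sum over the visiting walkers: sum_t (1 - N_best(t))
    tmax = int(finite.max())
    curve = learning_curve(finite, finite.size, np.arange(tmax + 1))
    area = float(np.sum(1.0 - curve))
    mean = float(np.mean(finite)) if frac_never == 0.0 else np.nan
    if frac_never > 0.0:
        warnings.warn(
            f"{frac_never:.1%} of walkers never visited the best target; "
            "MFPT undefined (conditional statistics only)",
            stacklevel=2,
        )
    return MFPTResult(mean=mean, area=area, fraction_never=frac_never)


def neighborhood_radius(L: int, N: int, override: float | None = None) -> float:
    """Cohesion radius r = L / (2 sqrt(N)).

    Half the mean distance between nearest neighbours of N points scattered
    uniformly on an L x L domain (which scales as L/sqrt(N)).
    """
    if override is not None:
        return float(override)
    if N < 1:
        raise ValueError(f"need N >= 1, got {N}")
    return L / (2.0 * np.sqrt(N))


def cohesion(positions: np.ndarray, r: float) -> float:
    """Mean number of other walkers within Euclidean distance r of a walker.

    Uses a k-d tree pair count rather than the dense pairwise matrix.
    """
    pts = np.asarray(positions, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"positions must be (N, 2), got {pts.shape}")
    N = pts.shape[0]
    if N == 1:
        return 0.0
    tree = cKDTree(pts)
    pairs = tree.count_neighbors(tree, r)  # ordered pairs incl. self-pairs
    return float((pairs - N) / N)


def asymptotic_cohesion(
    n_r: np.ndarray,
    window_frac: float = 0.1,
    slope_tol: float = 0.05,
) -> float:
    """Steady-state cohesion: mean of N_r(t) over the final window.

    Warns (rather than fails) when the last-window linear trend exceeds
    ``slope_tol`` in relative terms — the series may not have converged.
    """
    series = np.asarray(n_r, dtype=np.float64)
    if series.size < 10:
        raise ValueError(f"need >= 10 observations to estimate N_r_inf, got {series.size}")
    k = max(2, int(np.ceil(window_frac * series.size)))
    tail = series[-k:]
    value = float(tail.mean())
    if k >= 3 and value > 0:
        slope = np.polyfit(np.arange(k), tail, 1)[0]
        if abs(slope * k) > slope_tol * value:
            warnings.warn(
                "cohesion series still trending in the final window; "
                "N_r_inf estimate may not be stationary",
                stacklevel=2,
            )
    return value


def learning_time(
    obs_times: np.ndarray,
    n_r: np.ndarray,
    n_r_inf: float,
    window: int = 5,
) -> float | None:
    """First observed time at which smoothed N_r(t) reaches half of N_r_inf.

    The series is smoothed with a trailing moving average of ``window``
    observations.  Returns ``None`` when the half level is never reached or
    when no cohesion develops at all (``n_r_inf <= 0``).
    """
    if n_r_inf <= 0:
        return None
    times = np.asarray(obs_times)
    series = np.asarray(n_r, dtype=np.float64)
    if times.shape != series.shape:
        raise ValueError("obs_times and n_r must have matching shapes")
    w = max(1, int(window))
    kernel = np.ones(w)
    sums = np.convolve(series, kernel)[: series.size]
    lens = np.minimum(np.arange(series.size) + 1, w)
    smoothed = sums / lens
    hit = np.flatnonzero(smoothed >= n_r_inf / 2.0)
    if hit.size == 0:
        return None
    return float(times[hit[0]])
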