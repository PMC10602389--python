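"""Memory-decay kernels and preferential-recall sampling.

When a forager relocates from memory at time ``t`` it picks a past time
``t' in [0, t]`` with probability

    p_t(t') = F_t(t') / C(t),      C(t) = sum_{t'=0}^{t} F_t(t'),

and jumps back to the site it (or a peer) occupied at ``t'``.  The kernel
``F_t(t')`` depends only on the lag ``t - t'``:

* power family:        F = (t - t' + 1)^(-beta),  beta >= 0
* exponential family:  F ∝ exp(-(t - t' + 1) / delta_mem)
* uniform:             power with beta = 0 (linear preferential visits,
  i.e. non-decaying memory)

Because weights depend only on the lag, one cumulative lag table per kernel
serves every walker and every time step: sampling is a binary search over a
prefix of the table, O(log t) per draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KernelSpec",
    "recall_probabilities",
    "exponential_recall_probabilities",
    "sample_recall_time",
    "RecallSampler",
]

_FAMILIES = ("power", "exponential", "uniform")


@dataclass(frozen=True)
class KernelSpec:
    """Memory-kernel family and its single meaningful parameter.

    ``uniform`` is an alias for ``power`` with ``beta = 0``.
    """

    family: str = "power"
    beta: float = 0.0
    delta_mem: float | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}; use one of {_FAMILIES}")
        if self.family == "exponential":
            if self.delta_mem is None or self.delta_mem <= 0:
                raise ValueError("exponential kernel requires delta_mem > 0")
        else:
            if self.beta < 0:
                raise ValueError(f"power kernel requires beta >= 0, got {self.beta}")

    @property
    def effective_beta(self) -> float:
        return 0.0 if self.family == "uniform" else self.beta

    def lag_weights(self, n: int) -> np.ndarray:
        """Unnormalised kernel weights for lags ``0 .. n-1`` (lag = t - t')."""
        lags = np.arange(n, dtype=np.float64)
        if self.family == "exponential":
            return np.exp(-(lags + 1.0) / self.delta_mem)
        beta = self.effective_beta
        if beta == 0.0:
            return np.ones(n)
        return (lags + 1.0) ** (-beta)


def recall_probabilities(t: int, spec: KernelSpec) -> np.ndarray:
    """Normalised recall distribution over ``t' = 0 .. t`` at time ``t``.

    The returned vector is indexed by ``t'`` (not by lag), so for a decaying
    kernel it is non-decreasing: recent times are the most likely.
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    w = spec.lag_weights(t + 1)[::-1]  # lag t-t' reversed into t' order
    return w / w.sum()


def exponential_recall_probabilities(t: int, delta_mem: float) -> np.ndarray:
    """Recall distribution for the exponential kernel exp(-(t-t'+1)/Δ).

    The kernel prefactor cancels under normalisation.
    """
    return recall_probabilities(t, KernelSpec(family="exponential", delta_mem=delta_mem))


class RecallSampler:
    """Incremental cumulative lag table shared by all walkers of a run.

    The table ``S[k] = sum_{j<=k} F(lag=j)`` is extended geometrically as the
    simulation advances; a draw at time ``t`` inverts the CDF over lags
    ``0..t`` by binary search and returns ``t' = t - lag``.
    """

    def __init__(self, spec: KernelSpec, capacity: int = 1024):
        self.spec = spec
        self._uniform = spec.family != "exponential" and spec.effective_beta == 0.0
        self._cum = np.cumsum(spec.lag_weights(max(capacity, 2)))

    def _ensure(self, n: int) -> None:
        if n <= self._cum.size:
            return
        cap = max(n, 2 * self._cum.size)
        self._cum = np.cumsum(self.spec.lag_weights(cap))

    def sample(self, t: int, size: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``size`` recall times ``t'`` for current time ``t``."""
        if t < 0:
            raise ValueError(f"t must be >= 0, got {t}")
        if t == 0:
            return np.zeros(size, dtype=np.int64)
        if self._uniform:
            # exact shortcut: flat kernel is a uniform draw on [0, t]
            return rng.integers(0, t + 1, size=size)
        self._ensure(t + 1)
        cum = self._cum[: t + 1]
        u = rng.random(size) * cum[-1]
        lags = np.searchsorted(cum, u, side="right")
        return t - lags


def sample_recall_time(t: int, spec: KernelSpec, rng: np.random.Generator) -> int:
    """Single recall-time draw; marginal law equals :func:`recall_probabilities`."""
    return int(RecallSampler(spec, capacity=t + 1).sample(t, 1, rng)[0])
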