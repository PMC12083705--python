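"""Geometric shifting schedule for residual-shifting diffusion.

The forward process drifts a motion-free image ``x`` toward its
motion-corrupted counterpart ``y`` by mixing in a growing fraction
``beta_t`` of the residual ``r = y - x`` while injecting Gaussian noise
with variance ``gamma^2 * beta_t``.  The shifting sequence is a
non-uniform geometric interpolation between ``beta1`` (close to zero, so
the first state is essentially the clean image) and ``betaN`` (close to
one, so the last state is essentially the corrupted image plus noise):

    beta_t = beta1 * (betaN / beta1) ** (((t - 1) / (N - 1)) ** p)

for t = 1..N, with the convention ``beta_0 = 0`` so that the per-step
increments ``alpha_t = beta_t - beta_{t-1}`` telescope exactly and the
final reverse step is noiseless.  The exponent ``p`` controls the growth
rate: smaller ``p`` front-loads the noise (larger beta_t early in the
chain), larger ``p`` keeps early states cleaner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ScheduleConfig", "Schedule", "build_schedule", "noise_level"]

#: product gamma * sqrt(beta1) under the defaults; kept small so the first
#: diffusion state is statistically indistinguishable from the clean image.
DEFAULT_GAMMA_BETA1 = 0.04


@dataclass(frozen=True)
class ScheduleConfig:
    """Hyperparameters of the shifting sequence.

    Parameters
    ----------
    n_steps:
        Number of diffusion steps N (>= 2).  20 for training, 4 for the
        few-step sampler.
    beta1:
        First shifting coefficient, in (0, 1).  Default ``(0.04/gamma)**2``
        so that ``gamma * sqrt(beta1) = 0.04``.
    betaN:
        Last shifting coefficient, in (0, 1].  Default 0.999, close to the
        upper bound 1 at which the state mean coincides with ``y``.
    p:
        Growth-rate exponent (> 0), default 0.3.
    gamma:
        Global noise scale (> 0), default 2.
    """

    n_steps: int = 20
    gamma: float = 2.0
    beta1: float = field(default=None)  # type: ignore[assignment]
    betaN: float = 0.999
    p: float = 0.3

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if self.beta1 is None:
            object.__setattr__(
                self, "beta1", (DEFAULT_GAMMA_BETA1 / self.gamma) ** 2
            )
        if self.n_steps < 2:
            raise ValueError(f"n_steps must be >= 2, got {self.n_steps}")
        if not (0.0 < self.beta1 < 1.0):
            raise ValueError(f"beta1 must lie in (0, 1), got {self.beta1}")
        if not (0.0 < self.betaN <= 1.0):
            raise ValueError(f"betaN must lie in (0, 1], got {self.betaN}")
        if self.beta1 >= self.betaN:
            raise ValueError(
                "beta1 must be strictly smaller than betaN "
                f"(got beta1={self.beta1}, betaN={self.betaN})"
            )
        if self.p <= 0:
            raise ValueError(f"growth rate p must be positive, got {self.p}")

    def with_steps(self, n_steps: int) -> "ScheduleConfig":
        """Same endpoints/growth rate with a different step count.

        This is how the 4-step sampler derives its schedule from the
        20-step training configuration.
        """
        return ScheduleConfig(
            n_steps=n_steps,
            gamma=self.gamma,
            beta1=self.beta1,
            betaN=self.betaN,
            p=self.p,
        )


@dataclass(frozen=True)
class Schedule:
    """Precomputed shifting sequence.

    ``betas`` has length ``n_steps + 1`` with ``betas[0] == 0`` and
    ``betas[t]`` the coefficient at step t (1-based).  ``alphas`` has
    length ``n_steps + 1`` with ``alphas[0] = nan`` (undefined) and
    ``alphas[t] = betas[t] - betas[t-1]``.
    """

    betas: np.ndarray
    alphas: np.ndarray
    gamma: float
    config: ScheduleConfig

    @property
    def n_steps(self) -> int:
        return len(self.betas) - 1

    def beta(self, t: int) -> float:
        self._check_t(t, allow_zero=True)
        return float(self.betas[t])

    def alpha(self, t: int) -> float:
        self._check_t(t)
        return float(self.alphas[t])

    def _check_t(self, t: int, allow_zero: bool = False) -> None:
        lo = 0 if allow_zero else 1
        if not (lo <= t <= self.n_steps):
            raise IndexError(
                f"step index t={t} outside [{lo}, {self.n_steps}]"
            )


def build_schedule(cfg: ScheduleConfig) -> Schedule:
    """Construct the shifting sequence for ``cfg``.

    The sequence interpolates geometrically between ``beta1`` and
    ``betaN`` with warped exponent ``((t-1)/(N-1))**p``, so both endpoints
    are attained exactly; ``betas[0]`` is pinned to 0, which makes
    ``alpha_1 = beta_1`` and the final reverse step exact and noiseless.
    """
    n = cfg.n_steps
    t = np.arange(0, n + 1, dtype=float)
    warped = ((t[1:] - 1.0) / (n - 1.0)) ** cfg.p
    log_ratio = np.log(cfg.betaN) - np.log(cfg.beta1)
    betas = np.empty(n + 1)
    betas[0] = 0.0
    betas[1:] = cfg.beta1 * np.exp(warped * log_ratio)
    # pin endpoints against exp/log round-off
    betas[1] = cfg.beta1
    betas[n] = cfg.betaN
    # Strictly increasing analytically for every p > 0; in float64 an
    # extreme growth rate (e.g. p = 10 at large N) can underflow the first
    # increment to a tie, which is tolerated.  A decrease means a bad config.
    if np.any(np.diff(betas) < 0):
        raise ValueError("schedule is not increasing; check config")
    alphas = np.empty(n + 1)
    alphas[0] = np.nan
    alphas[1:] = np.diff(betas)
    betas.setflags(write=False)
    alphas.setflags(write=False)
    return Schedule(betas=betas, alphas=alphas, gamma=cfg.gamma, config=cfg)


def noise_level(sched: Schedule, t: int) -> float:
    """Dimensionless noise magnitude ``sqrt(beta_t)`` at step t.

    Used to condition the denoiser: conditioning on the continuous level
    rather than the integer index lets a model trained under an N=20
    schedule serve an N=4 sampler whose beta values differ.
    """
    sched._check_t(t)
    return float(np.sqrt(sched.betas[t]))
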