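"""Residual-shifting diffusion: forward process, posterior, loss, sampler.

Instead of diffusing the clean image x to white noise, the forward chain
drifts it toward the motion-corrupted image y through the residual
r = y - x:

    q(x_t | x_{t-1}, y) = N(x_t; x_{t-1} + alpha_t r, gamma^2 alpha_t I)
    q(x_t | x, y)       = N(x_t; x + beta_t r,       gamma^2 beta_t  I)

with beta_t the shifting sequence and alpha_t = beta_t - beta_{t-1} its
increments.  Because the terminal state x_N is (up to noise) the corrupted
image itself, the reverse chain has a short distance to travel and a
handful of steps suffice.  The reverse kernel is Gaussian with the
closed-form posterior parameters

    mean = (beta_{t-1}/beta_t) x_t + (alpha_t/beta_t) x0
    var  = gamma^2 (beta_{t-1}/beta_t) alpha_t

where the network's estimate of the clean image stands in for x0 during
sampling; the residual cancels out of the posterior, so the sampler never
needs to know r.  With beta_0 = 0 the final step collapses to the network
prediction exactly and is noiseless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence, runtime_checkable

import numpy as np

from .schedule import Schedule, noise_level

__all__ = [
    "PairedSample",
    "DiffusionState",
    "LossValue",
    "DenoiserProtocol",
    "forward_marginal_params",
    "sample_forward",
    "transition_sample",
    "posterior_params",
    "training_loss",
    "training_step",
    "sample_restore",
]


@dataclass
class PairedSample:
    """A motion-free image x, its corrupted counterpart y, and r = y - x."""

    x: np.ndarray
    y: np.ndarray
    r: np.ndarray = field(default=None)  # type: ignore[assignment]
    level: Optional[str] = None
    seed: Optional[int] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError(
                f"x and y must share a grid, got {self.x.shape} vs {self.y.shape}"
            )
        if self.r is None:
            self.r = self.y - self.x
        else:
            self.r = np.asarray(self.r, dtype=float)
            if not np.array_equal(self.r, self.y - self.x):
                raise ValueError("r must equal y - x elementwise")


@dataclass(frozen=True)
class DiffusionState:
    """Noisy state x_t at step t of the forward chain."""

    x_t: np.ndarray
    t: int


@dataclass(frozen=True)
class LossValue:
    """Training loss split into its l2 and l1 components (equal weighting)."""

    total: float
    l2_part: float
    l1_part: float


@runtime_checkable
class DenoiserProtocol(Protocol):
    """What the sampler and training loop require of a denoiser.

    ``predict`` maps (x_t, y, noise level sqrt(beta_t)) to an estimate of
    the clean image; ``gamma`` (may be None) is the noise scale of the
    schedule the model was trained under.
    """

    gamma: Optional[float]

    def predict(
        self, x_t: np.ndarray, y: np.ndarray, level: float
    ) -> np.ndarray: ...


def _check_step(sched: Schedule, t: int) -> None:
    if not (1 <= t <= sched.n_steps):
        raise IndexError(f"step t={t} outside [1, {sched.n_steps}]")


def forward_marginal_params(
    sample: PairedSample, sched: Schedule, t: int
) -> tuple[np.ndarray, float]:
    """Mean x + beta_t r and scalar std gamma*sqrt(beta_t) of q(x_t|x, y)."""
    _check_step(sched, t)
    beta = sched.betas[t]
    mean = sample.x + beta * sample.r
    std = sched.gamma * float(np.sqrt(beta))
    return mean, std


def sample_forward(
    sample: PairedSample,
    sched: Schedule,
    t: int,
    rng: np.random.Generator,
) -> DiffusionState:
    """Draw x_t ~ q(x_t | x, y) directly from the marginal."""
    mean, std = forward_marginal_params(sample, sched, t)
    eps = rng.standard_normal(mean.shape)
    return DiffusionState(x_t=mean + std * eps, t=t)


def transition_sample(
    x_prev: np.ndarray,
    r: np.ndarray,
    sched: Schedule,
    t: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One forward step x_{t-1} -> x_t through the transition kernel."""
    _check_step(sched, t)
    if x_prev.shape != r.shape:
        raise ValueError("x_prev and r must share a grid")
    alpha = sched.alphas[t]
    eps = rng.standard_normal(x_prev.shape)
    return x_prev + alpha * r + sched.gamma * np.sqrt(alpha) * eps


def posterior_params(
    x_t: np.ndarray,
    x0_est: np.ndarray,
    sched: Schedule,
    t: int,
) -> tuple[np.ndarray, float]:
    """Mean and scalar variance of the reverse posterior q(x_{t-1}|x_t, x0).

    The residual cancels, so only the current state and a clean-image
    estimate enter.  At t = 1 (beta_0 = 0) the posterior collapses onto
    x0_est with zero variance, making the last reverse step exact.
    """
    _check_step(sched, t)
    if x_t.shape != x0_est.shape:
        raise ValueError("x_t and x0_est must share a grid")
    beta_prev = sched.betas[t - 1]
    beta = sched.betas[t]
    alpha = sched.alphas[t]
    mean = (beta_prev / beta) * x_t + (alpha / beta) * x0_est
    var = sched.gamma**2 * (beta_prev / beta) * alpha
    return mean, float(var)


def training_loss(
    f_out: np.ndarray, x: np.ndarray, l2_only: bool = False
) -> LossValue:
    """Combined l2 + l1 loss between the network output and the clean image.

    Both norms are reduced as means over pixels and weighted 1:1; the
    ``l2_only`` switch drops the l1 term (the ablation mode).
    """
    if f_out.shape != x.shape:
        raise ValueError("f_out and x must share a grid")
    d = f_out - x
    l2 = float(np.mean(d**2))
    l1 = 0.0 if l2_only else float(np.mean(np.abs(d)))
    return LossValue(total=l2 + l1, l2_part=l2, l1_part=l1)


def training_step(
    batch: Sequence[PairedSample],
    model,
    sched: Schedule,
    rng: np.random.Generator,
    l2_only: bool = False,
) -> LossValue:
    """One stochastic training update.

    Per batch element draws t ~ Uniform{1..N}, forms x_t from the forward
    marginal, and takes one optimizer step on the combined loss of
    f(x_t, y, sqrt(beta_t)) against the clean image.  Delegates the
    gradient computation and parameter update to ``model.train_batch``.
    """
    if len(batch) == 0:
        raise ValueError("batch must be non-empty")
    if getattr(model, "gamma", None) is not None and model.gamma != sched.gamma:
        raise ValueError(
            f"model gamma {model.gamma} != schedule gamma {sched.gamma}"
        )
    ts = rng.integers(1, sched.n_steps + 1, size=len(batch))
    x_t = np.stack(
        [
            sample_forward(s, sched, int(t), rng).x_t
            for s, t in zip(batch, ts)
        ]
    )
    y = np.stack([s.y for s in batch])
    x = np.stack([s.x for s in batch])
    levels = np.sqrt(sched.betas[ts])
    loss = model.train_batch(x_t, y, levels, x, l2_only=l2_only)
    if not np.isfinite(loss.total):
        raise FloatingPointError(
            f"non-finite training loss {loss} at steps t={ts.tolist()}"
        )
    return loss


def sample_restore(
    y: np.ndarray,
    model: DenoiserProtocol,
    sampler_sched: Schedule,
    rng: np.random.Generator,
    return_trajectory: bool = False,
):
    """Few-step reverse diffusion restoring a clean image from y.

    Initializes x_N ~ N(y, gamma^2 beta_N I), then for t = N..1 computes
    the posterior mean around the network's clean-image estimate and adds
    Gaussian noise with std gamma*sqrt(beta_{t-1} alpha_t / beta_t) — zero
    at the final step.  Exactly N denoiser evaluations.
    """
    y = np.asarray(y, dtype=float)
    if getattr(model, "gamma", None) is not None and (
        model.gamma != sampler_sched.gamma
    ):
        raise ValueError(
            f"model gamma {model.gamma} != sampler gamma {sampler_sched.gamma}"
        )
    n = sampler_sched.n_steps
    gamma = sampler_sched.gamma
    x_t = y + gamma * np.sqrt(sampler_sched.betas[n]) * rng.standard_normal(
        y.shape
    )
    trajectory = [x_t]
    for t in range(n, 0, -1):
        x0_est = model.predict(x_t, y, noise_level(sampler_sched, t))
        mean, var = posterior_params(x_t, x0_est, sampler_sched, t)
        if t > 1:
            x_t = mean + np.sqrt(var) * rng.standard_normal(y.shape)
        else:
            x_t = mean
        trajectory.append(x_t)
    if return_trajectory:
        return x_t, trajectory
    return x_t
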