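"""End-to-end orchestration: fixtures -> train -> correct -> evaluate.

``run_pipeline`` drives the full desk-scale experiment from a single
RunConfig and a single seed: generate phantom fixtures, corrupt them at
every severity level, train the denoiser under the long training
schedule, restore the held-out split with the short sampler schedule,
and score the result.  Every stage derives its randomness from the one
seed and the manifest records enough metadata to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import __version__
from .denoiser import DenoiserModel, SPEC_PRESETS, build_denoiser
from .diffusion import LossValue, PairedSample, sample_restore, training_step
from .metrics import MetricsReport, evaluate_pairs
from .motionsim import LEVELS
from .phantoms import PhantomConfig, make_fixture_suite
from .schedule import Schedule, ScheduleConfig, build_schedule

__all__ = ["RunConfig", "fit", "restore_samples", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything one pipeline run depends on; one seed governs it all."""

    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    sampler_steps: int = 4
    arch: str = "tiny"
    n_phantoms: int = 20
    image_size: int = 64
    levels: tuple = LEVELS
    train_steps: int = 2000
    batch_size: int = 2
    lr: float = 2e-3
    l2_only: bool = False
    seed: int = 0
    normalization: str = "per-slice max to [0, 1]"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "schedule" in raw:
            raw["schedule"] = ScheduleConfig(**raw["schedule"])
        if "levels" in raw:
            raw["levels"] = tuple(raw["levels"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["levels"] = list(self.levels)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def fit(
    model: DenoiserModel,
    samples: Sequence[PairedSample],
    sched: Schedule,
    n_steps: int,
    batch_size: int,
    rng: np.random.Generator,
    l2_only: bool = False,
    log_every: Optional[int] = None,
    lr_decay: float = 0.1,
    ema_decay: Optional[float] = 0.995,
) -> list[LossValue]:
    """Stochastic training loop: random minibatches, one update per step.

    The learning rate follows a cosine anneal from the model's base rate
    down to ``lr_decay`` times it, and the weights handed back are an
    exponential moving average of the trajectory (``ema_decay``; pass
    None to keep the last iterate) — the standard recipe for diffusion
    training at this scale.
    """
    losses: list[LossValue] = []
    lr0 = model.lr
    for step in range(n_steps):
        if lr_decay < 1.0 and n_steps > 1:
            cos = 0.5 * (1 + np.cos(np.pi * step / (n_steps - 1)))
            model.lr = lr0 * (lr_decay + (1 - lr_decay) * cos)
        idx = rng.choice(len(samples), size=min(batch_size, len(samples)),
                         replace=len(samples) < batch_size)
        batch = [samples[i] for i in idx]
        loss = training_step(batch, model, sched, rng, l2_only=l2_only)
        losses.append(loss)
        if ema_decay is not None:
            model.ema_update(ema_decay)
        if log_every and (step + 1) % log_every == 0:
            recent = np.mean([l.total for l in losses[-log_every:]])
            print(f"  step {step + 1:>5d}/{n_steps}  loss {recent:.4f}")
    if ema_decay is not None:
        model.swap_in_ema()
    return losses


def restore_samples(
    model: DenoiserModel,
    samples: Sequence[PairedSample],
    sampler_sched: Schedule,
    rng: np.random.Generator,
    clip: Optional[tuple[float, float]] = (0.0, 1.0),
) -> list[np.ndarray]:
    """Run the few-step sampler on the corrupted image of every pair.

    Outputs are clipped into the normalization range by default: the
    references are magnitude images scaled to [0, 1], so values outside
    it are sampling overshoot, not signal.
    """
    out = [sample_restore(s.y, model, sampler_sched, rng) for s in samples]
    if clip is not None:
        out = [np.clip(o, *clip) for o in out]
    return out


def _suite_digest(suite: dict) -> str:
    h = hashlib.sha256()
    for split in sorted(suite):
        for s in suite[split]:
            h.update(np.ascontiguousarray(s.x).tobytes())
            h.update(np.ascontiguousarray(s.y).tobytes())
    return h.hexdigest()[:16]


def run_pipeline(
    config: RunConfig,
    outdir,
    force: bool = False,
    verbose: bool = True,
) -> dict:
    """Run fixtures -> train -> correct -> evaluate; write artifacts.

    Returns a summary dict with the per-level corrupted-baseline and
    restored metrics.  Refuses to overwrite an existing manifest unless
    ``force`` is given.
    """
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists() and not force:
        raise FileExistsError(
            f"{manifest_path} exists; pass force=True to redo the run"
        )
    outdir.mkdir(parents=True, exist_ok=True)

    t0 = time.time()
    say = print if verbose else (lambda *a, **k: None)

    say(f"[1/4] fixtures: {config.n_phantoms} phantoms at "
        f"{config.image_size}x{config.image_size}, levels {list(config.levels)}")
    suite = make_fixture_suite(
        config.n_phantoms,
        PhantomConfig(size=config.image_size),
        levels=config.levels,
        seed=config.seed,
    )
    fixture_hash = _suite_digest(suite)

    say(f"[2/4] train: arch={config.arch}, {config.train_steps} steps, "
        f"batch {config.batch_size}")
    train_sched = build_schedule(config.schedule)
    model = build_denoiser(
        config.arch,
        seed=config.seed,
        schedule_config=config.schedule,
        lr=config.lr,
    )
    rng = np.random.default_rng(config.seed + 1)
    losses = fit(
        model,
        suite["train"],
        train_sched,
        config.train_steps,
        config.batch_size,
        rng,
        l2_only=config.l2_only,
        log_every=max(1, config.train_steps // 10) if verbose else None,
    )
    ckpt_path = outdir / "denoiser.npz"
    model.save(ckpt_path)

    say(f"[3/4] correct: {config.sampler_steps}-step sampler on "
        f"{len(suite['test'])} held-out pairs")
    sampler_sched = build_schedule(
        config.schedule.with_steps(config.sampler_steps)
    )
    restore_rng = np.random.default_rng(config.seed + 2)
    restored = restore_samples(model, suite["test"], sampler_sched, restore_rng)

    say("[4/4] evaluate")
    report = evaluate_pairs(suite["test"], restored)
    baseline = evaluate_pairs(suite["test"], [s.y for s in suite["test"]])
    report.to_csv(outdir / "metrics_restored.csv")
    report.to_json(outdir / "metrics_restored.json")
    baseline.to_csv(outdir / "metrics_corrupted.csv")
    baseline.to_json(outdir / "metrics_corrupted.json")

    summary = {
        "restored": report.aggregate(),
        "corrupted": baseline.aggregate(),
        "final_loss": float(np.mean([l.total for l in losses[-50:]])),
        "n_train_pairs": len(suite["train"]),
        "n_test_pairs": len(suite["test"]),
    }
    manifest = {
        "config": json.loads(json.dumps(asdict(config), default=str)),
        "config_digest": config.digest(),
        "fixture_digest": fixture_hash,
        "seed": config.seed,
        "package_version": __version__,
        "numpy_version": np.__version__,
        "n_model_params": model.n_params,
        "runtime_s": round(time.time() - t0, 1),
        "summary": summary,
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    if verbose:
        for level in config.levels:
            rn = summary["restored"][level]["nmse_pct"]["mean"]
            cn = summary["corrupted"][level]["nmse_pct"]["mean"]
            rs = summary["restored"][level]["ssim"]["mean"]
            cs = summary["corrupted"][level]["ssim"]["mean"]
            say(f"  {level:>8s}: NMSE {cn:.3f}% -> {rn:.3f}%   "
                f"SSIM {cs:.4f} -> {rs:.4f}")
    return manifest


def selftest_config(seed: int = 0, micro: bool = False) -> RunConfig:
    """Preconfigured smoke profile; ``micro`` shrinks it to seconds."""
    if micro:
        return RunConfig(
            n_phantoms=4, train_steps=30, batch_size=2, seed=seed
        )
    return RunConfig(seed=seed)
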