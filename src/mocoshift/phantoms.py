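"""Seeded brain-like phantoms for building and testing without data downloads.

Each phantom mimics the gross intensity structure of a T1-weighted brain
slice: a bright outer annulus (subcutaneous fat / skull analogue, which
makes ghosting visible outside the head), mid-intensity parenchyma with a
smooth low-frequency modulation, and a handful of random elliptical
inclusions, some dark (ventricle-like) and some bright.  Values live in
[0, 1] on a square grid whose edge is divisible by the denoiser pyramid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy import ndimage

from .diffusion import PairedSample
from .motionsim import LEVELS, MotionConfig, corrupt

__all__ = ["PhantomConfig", "make_phantom", "make_fixture_suite"]


@dataclass(frozen=True)
class PhantomConfig:
    size: int = 64
    n_ellipses: tuple[int, int] = (4, 8)
    skull_ring: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 32:
            raise ValueError("size must be at least 32")
        lo, hi = self.n_ellipses
        if not (0 <= lo <= hi):
            raise ValueError(f"bad n_ellipses range {self.n_ellipses}")


def _ellipse_mask(
    yy: np.ndarray,
    xx: np.ndarray,
    center: tuple[float, float],
    axes: tuple[float, float],
    angle: float,
) -> np.ndarray:
    cy, cx = center
    ay, ax = axes
    c, s = np.cos(angle), np.sin(angle)
    u = (yy - cy) * c + (xx - cx) * s
    v = -(yy - cy) * s + (xx - cx) * c
    return (u / ay) ** 2 + (v / ax) ** 2 <= 1.0


def make_phantom(cfg: PhantomConfig) -> np.ndarray:
    """Deterministic brain-like magnitude slice in [0, 1]."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.size
    ax = np.linspace(-1.0, 1.0, n)
    yy, xx = np.meshgrid(ax, ax, indexing="ij")

    img = np.zeros((n, n))
    head_axes = (
        0.78 + 0.05 * rng.uniform(-1, 1),
        0.68 + 0.05 * rng.uniform(-1, 1),
    )
    head = _ellipse_mask(yy, xx, (0.0, 0.0), head_axes, 0.0)
    ring_axes = (head_axes[0] - 0.09, head_axes[1] - 0.09)
    interior = _ellipse_mask(yy, xx, (0.0, 0.0), ring_axes, 0.0)

    if cfg.skull_ring:
        img[head] = 0.85 + 0.1 * rng.uniform()
    # parenchyma with a smooth low-frequency modulation
    base = 0.42 + 0.05 * rng.uniform(-1, 1)
    mod = 0.06 * np.sin(
        np.pi * (yy * rng.uniform(0.5, 1.5) + rng.uniform(0, 2))
    ) * np.cos(np.pi * (xx * rng.uniform(0.5, 1.5) + rng.uniform(0, 2)))
    img[interior] = base + mod[interior]

    n_ell = int(rng.integers(cfg.n_ellipses[0], cfg.n_ellipses[1] + 1))
    for i in range(n_ell):
        center = tuple(rng.uniform(-0.45, 0.45, size=2))
        axes = tuple(rng.uniform(0.05, 0.28, size=2))
        angle = rng.uniform(0, np.pi)
        mask = _ellipse_mask(yy, xx, center, axes, angle) & interior
        if i < 2:  # ventricle-like dark inclusions first
            val = rng.uniform(0.08, 0.18)
        else:
            val = rng.uniform(0.30, 0.68)
        img[mask] = val

    img = ndimage.gaussian_filter(img, sigma=0.7)
    return np.clip(img, 0.0, 1.0)


def make_fixture_suite(
    n: int,
    cfg: Optional[PhantomConfig] = None,
    levels: Iterable[str] = LEVELS,
    seed: int = 0,
    splits: tuple[float, float, float] = (0.6, 0.2, 0.2),
    motion_configs: Optional[dict] = None,
) -> dict:
    """Disjoint train/val/test collections of corrupted pairs.

    Generates ``n`` phantoms with per-phantom seeds derived from ``seed``,
    partitions them disjointly into three splits, and corrupts every
    phantom at every severity level.  Each PairedSample records its
    phantom seed, corruption seed, severity label, and slab plan.
    """
    if n < 3:
        raise ValueError("need n >= 3 phantoms to form three splits")
    cfg = cfg or PhantomConfig()
    levels = list(levels)
    rng = np.random.default_rng(seed)

    n_train = max(1, int(round(splits[0] * n)))
    n_val = max(1, int(round(splits[1] * n)))
    n_train = min(n_train, n - 2)
    n_val = min(n_val, n - n_train - 1)
    counts = {"train": n_train, "val": n_val, "test": n - n_train - n_val}

    phantom_seeds = [int(s) for s in rng.integers(2**31, size=n)]
    suite: dict[str, list[PairedSample]] = {}
    idx = 0
    for split, count in counts.items():
        samples: list[PairedSample] = []
        for _ in range(count):
            pseed = phantom_seeds[idx]
            idx += 1
            img = make_phantom(
                PhantomConfig(
                    size=cfg.size,
                    n_ellipses=cfg.n_ellipses,
                    skull_ring=cfg.skull_ring,
                    seed=pseed,
                )
            )
            for level in levels:
                mcfg = (motion_configs or {}).get(level) or MotionConfig.preset(
                    level
                )
                cseed = int(rng.integers(2**31))
                y, plan = corrupt(img, mcfg, np.random.default_rng(cseed))
                samples.append(
                    PairedSample(
                        x=img,
                        y=y,
                        level=level,
                        seed=cseed,
                        meta={"phantom_seed": pseed, "plan": plan.to_dict()},
                    )
                )
        suite[split] = samples
    return suite
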