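"""Paired image-quality metrics: NMSE, PSNR, SSIM, Pearson correlation.

NMSE is reported in percent (100 * ||test - ref||^2 / ||ref||^2); PSNR in
dB with an infinity sentinel for identical images; SSIM uses the standard
11x11 Gaussian window (sigma 1.5, K1=0.01, K2=0.03); Pearson is the
product-moment correlation over flattened pixels.  Unless given, the data
range for PSNR/SSIM is the maximum of the reference image of each pair.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage.metrics import structural_similarity

from .diffusion import PairedSample

__all__ = [
    "nmse",
    "psnr",
    "ssim",
    "pearson",
    "evaluate_pairs",
    "MetricsReport",
]


def _check_pair(ref: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    if ref.shape != test.shape:
        raise ValueError(f"grid mismatch: {ref.shape} vs {test.shape}")
    return ref, test


def nmse(ref: np.ndarray, test: np.ndarray) -> float:
    """Normalized mean squared error in percent; lower is better."""
    ref, test = _check_pair(ref, test)
    denom = float(np.sum(ref**2))
    if denom == 0.0:
        raise ValueError("reference image is identically zero")
    return 100.0 * float(np.sum((test - ref) ** 2)) / denom


def psnr(ref: np.ndarray, test: np.ndarray, data_range: Optional[float] = None) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    ref, test = _check_pair(ref, test)
    if data_range is None:
        data_range = float(ref.max())
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    mse = float(np.mean((test - ref) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * float(np.log10(data_range**2 / mse))


def ssim(ref: np.ndarray, test: np.ndarray, data_range: Optional[float] = None) -> float:
    """Mean structural similarity with the Gaussian-window parameterization.

    11x11 Gaussian window, sigma = 1.5, K1 = 0.01, K2 = 0.03 — the
    configuration of Wang et al. that standard evaluation libraries
    default to.
    """
    ref, test = _check_pair(ref, test)
    if min(ref.shape) < 11:
        raise ValueError("grid smaller than the 11x11 SSIM window")
    if data_range is None:
        data_range = float(ref.max())
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    return float(
        structural_similarity(
            ref,
            test,
            data_range=data_range,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
    )


def pearson(ref: np.ndarray, test: np.ndarray) -> float:
    """Pixel-wise product-moment correlation over flattened images."""
    ref, test = _check_pair(ref, test)
    a = ref.ravel()
    b = test.ravel()
    if np.var(a) == 0.0 or np.var(b) == 0.0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class MetricsReport:
    """Per-pair metrics with mean +/- std aggregation per severity level."""

    rows: list[dict] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.rows)

    def aggregate(self) -> dict:
        """mean/std of each metric, overall and per severity level."""
        out: dict[str, dict] = {}
        levels = sorted({r["level"] for r in self.rows}, key=str)
        for level in ["all", *levels]:
            rows = (
                self.rows
                if level == "all"
                else [r for r in self.rows if r["level"] == level]
            )
            stats = {}
            for key in ("psnr_db", "ssim", "nmse_pct", "pearson_rho"):
                vals = np.array([r[key] for r in rows], dtype=float)
                finite = vals[np.isfinite(vals)]
                stats[key] = {
                    "mean": float(np.mean(finite)) if finite.size else float("nan"),
                    "std": float(np.std(finite)) if finite.size else float("nan"),
                    "n": int(len(rows)),
                }
            out[str(level)] = stats
        return out

    def to_csv(self, path) -> None:
        fields = ["index", "level", "psnr_db", "ssim", "nmse_pct", "pearson_rho"]
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=fields)
            writer.writeheader()
            for row in self.rows:
                writer.writerow({k: row[k] for k in fields})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"per_pair": self.rows, "aggregate": self.aggregate()},
                fh,
                indent=2,
                default=float,
            )


def evaluate_pairs(
    samples: Sequence[PairedSample],
    restored: Sequence[np.ndarray],
    data_range: Optional[float] = None,
) -> MetricsReport:
    """Score restored images against the clean references of their pairs.

    One restored image per sample is required; each row carries the
    sample's severity label so the report can aggregate per level.
    """
    if len(samples) != len(restored):
        raise ValueError(
            f"{len(samples)} samples but {len(restored)} restored images"
        )
    report = MetricsReport()
    for i, (s, out) in enumerate(zip(samples, restored)):
        report.rows.append(
            {
                "index": i,
                "level": s.level if s.level is not None else "unknown",
                "psnr_db": psnr(s.x, out, data_range),
                "ssim": ssim(s.x, out, data_range),
                "nmse_pct": nmse(s.x, out),
                "pearson_rho": pearson(s.x, out),
            }
        )
    return report
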