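"""File I/O: NIfTI volumes, PNG slices, and per-slice intensity scaling."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image as PILImage

__all__ = [
    "load_image",
    "save_image",
    "normalize_slice",
    "denormalize_slice",
]


def load_image(path) -> np.ndarray:
    """Read a 2-D slice (PNG) or 2-D/3-D volume (NIfTI) as float64.

    PNGs are scaled by their bit-depth maximum into [0, 1]; NIfTI data is
    returned in its stored units.
    """
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return np.asarray(nib.load(str(path)).get_fdata(), dtype=float)
    if name.endswith(".png"):
        img = PILImage.open(path)
        arr = np.asarray(img, dtype=float)
        if arr.ndim == 3:  # collapse RGB(A) to luminance
            arr = arr[..., :3].mean(axis=-1)
        peak = 65535.0 if arr.max() > 255 else 255.0
        return arr / peak
    raise ValueError(f"unsupported image format: {path.name}")


def save_image(path, arr: np.ndarray) -> None:
    """Write NIfTI (any dimensionality, identity affine) or 16-bit PNG."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(arr, dtype=float)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        nib.save(nib.Nifti1Image(arr, affine=np.eye(4)), str(path))
        return
    if name.endswith(".png"):
        if arr.ndim != 2:
            raise ValueError("PNG output requires a 2-D slice")
        lo, hi = float(arr.min()), float(arr.max())
        scale = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
        PILImage.fromarray(
            np.round(scale * 65535).astype(np.uint16)
        ).save(path)
        return
    raise ValueError(f"unsupported image format: {path.name}")


def normalize_slice(img: np.ndarray) -> tuple[np.ndarray, float]:
    """Scale a slice by its own maximum into [0, 1]; returns the scale."""
    img = np.asarray(img, dtype=float)
    peak = float(img.max())
    if peak <= 0:
        return np.zeros_like(img), 1.0
    return img / peak, peak


def denormalize_slice(img: np.ndarray, peak: float) -> np.ndarray:
    return np.asarray(img, dtype=float) * peak
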