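"""Image preprocessing ahead of feature extraction.

Order of application in the pipeline: z-score normalization (anatomical
gray-level images only) → resampling to 1 mm³ → physiological thresholding
(quantitative maps) → fixed-bin-width discretization → extraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage


@dataclass(frozen=True)
class DiscretizationSpec:
    """Fixed-bin-width discretization over a declared value range."""

    vmin: float
    vmax: float
    bin_width: float

    def __post_init__(self):
        if self.bin_width <= 0 or self.vmax <= self.vmin:
            raise ValueError("invalid discretization spec")

    @property
    def n_bins(self) -> int:
        return math.ceil((self.vmax - self.vmin) / self.bin_width)


def znormalize(image: np.ndarray, clip_range: tuple | None = None) -> np.ndarray:
    """Z-score normalization: subtract the mean, divide by the std.

    The result has mean 0 and unit standard deviation with an expected
    range of roughly [−3, 3]; values outside are kept unless ``clip_range``
    is given.  Raises on a constant image.
    """
    image = np.asarray(image, dtype=float)
    std = image.std()
    if std == 0:
        raise ValueError("cannot z-normalize a constant image")
    out = (image - image.mean()) / std
    if clip_range is not None:
        out = np.clip(out, *clip_range)
    return out


def discretize(image: np.ndarray, spec: DiscretizationSpec,
               mask: np.ndarray | None = None) -> tuple[np.ndarray, int]:
    """Map values to integer gray levels 1..n_bins.

    level(v) = floor((v − vmin)/width) + 1, capped at the bin count;
    values below the range floor within the mask are assigned level 1.
    Voxels outside ``mask`` get level 0.  Returns ``(levels, n_bins)``.
    """
    image = np.asarray(image, dtype=float)
    n = spec.n_bins
    levels = np.floor((image - spec.vmin) / spec.bin_width).astype(np.int32) + 1
    levels = np.clip(levels, 1, n)
    if mask is not None:
        levels = np.where(np.asarray(mask, dtype=bool), levels, 0).astype(np.int32)
    return levels, n


def _to_sitk(array: np.ndarray, spacing) -> sitk.Image:
    # SimpleITK uses (z, y, x) array order; keep (x, y, z) at the API surface
    img = sitk.GetImageFromArray(np.ascontiguousarray(array.T))
    img.SetSpacing(tuple(float(s) for s in spacing))
    return img


def resample_isotropic(array: np.ndarray, spacing, out_spacing: float = 1.0,
                       is_mask: bool = False) -> tuple[np.ndarray, tuple]:
    """Resample to an isotropic grid (default 1×1×1 mm).

    Trilinear interpolation for images, nearest-neighbor for masks.
    Returns ``(resampled, new_spacing)``.
    """
    if spacing is None or len(spacing) != array.ndim:
        raise ValueError("valid per-axis spacing metadata required")
    spacing = tuple(float(s) for s in spacing)
    if all(abs(s - out_spacing) < 1e-9 for s in spacing):
        out = array.astype(bool) if is_mask else np.asarray(array, dtype=float)
        return out.copy(), spacing
    img = _to_sitk(np.asarray(array, dtype=float), spacing)
    new_size = [int(round(n * s / out_spacing)) for n, s in zip(array.shape, spacing)]
    res = sitk.Resample(
        img, new_size, sitk.Transform(),
        sitk.sitkNearestNeighbor if is_mask else sitk.sitkLinear,
        img.GetOrigin(), (out_spacing,) * 3, img.GetDirection(), 0.0,
        sitk.sitkFloat64,
    )
    out = sitk.GetArrayFromImage(res).T
    if is_mask:
        out = out > 0.5
    return out, (out_spacing,) * 3


def log_filter(image: np.ndarray, sigma_mm: float = 1.0,
               spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Laplacian-of-Gaussian edge enhancement at scale ``sigma_mm``."""
    if sigma_mm <= 0:
        raise ValueError("sigma must be positive")
    sigma_vox = [sigma_mm / s for s in spacing]
    return ndimage.gaussian_laplace(np.asarray(image, dtype=float), sigma_vox)
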