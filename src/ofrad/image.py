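"""Image containers, NIfTI I/O, resampling, normalization and gray-level discretization.

All volumes are plain ``numpy`` arrays indexed ``(x, y, z)`` with voxel centres at
``origin + index * spacing``; spacing is in millimetres.  The preprocessing chain
mirrors standard radiomics practice: resample image+mask to an isotropic 2 mm grid,
normalize intensities inside the ROI (min–max to [0, 1] or z-score), then bin the
ROI intensities into ``n_levels`` equal-width gray levels for the texture matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

from .exceptions import DegenerateROIError, FormatError

__all__ = [
    "ImageVolume",
    "ROIMask",
    "DiscretizedVolume",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "resample_isotropic",
    "normalize_minmax",
    "normalize_zscore",
    "discretize",
]


@dataclass
class ImageVolume:
    """A 3D scalar grid with voxel spacing (mm) and origin (mm)."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise FormatError(f"expected a 3D volume, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("volume contains non-finite values")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise FormatError(f"spacing must be 3 positive values, got {self.spacing_mm}")
        self.origin_mm = tuple(float(o) for o in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass
class ROIMask:
    """Binary volume on the same grid as its companion image."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values) > 0.5
        if self.values.ndim != 3:
            raise FormatError(f"expected a 3D mask, got ndim={self.values.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise FormatError(f"spacing must be 3 positive values, got {self.spacing_mm}")
        self.origin_mm = tuple(float(o) for o in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3


@dataclass
class DiscretizedVolume:
    """Integer gray-level labels: 0 outside the ROI, 1..n_levels inside."""

    labels: np.ndarray
    n_levels: int
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    degenerate: bool = field(default=False)

    @property
    def roi(self) -> np.ndarray:
        return self.labels > 0


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _load_nifti(path):
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3D data, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise FormatError(f"{path}: invalid voxel spacing {zooms}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return np.asarray(data, dtype=np.float64), tuple(float(z) for z in zooms), origin


def read_volume(path) -> ImageVolume:
    values, spacing, origin = _load_nifti(path)
    return ImageVolume(values, spacing, origin)


def read_mask(path) -> ROIMask:
    """Read a mask volume, binarizing at 0.5 (so {0, 255} encodings work)."""
    values, spacing, origin = _load_nifti(path)
    return ROIMask(values > 0.5, spacing, origin)


def _affine(spacing, origin):
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def write_volume(img: ImageVolume, path) -> None:
    nib.save(nib.Nifti1Image(img.values.astype(np.float32), _affine(img.spacing_mm, img.origin_mm)), str(path))


def write_mask(mask: ROIMask, path) -> None:
    nib.save(nib.Nifti1Image(mask.values.astype(np.uint8), _affine(mask.spacing_mm, mask.origin_mm)), str(path))


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_isotropic(
    img: ImageVolume, mask: ROIMask, target_mm: float = 2.0
) -> tuple[ImageVolume, ROIMask]:
    """Resample an image/mask pair to an isotropic ``target_mm`` grid.

    The image is interpolated trilinearly and the mask by nearest neighbour,
    both over the extent of the original grid.  Inputs already on the target
    grid are returned unchanged (bit-identical).
    """
    if img.shape != mask.shape or img.spacing_mm != mask.spacing_mm:
        raise FormatError("image and mask must share grid dimensions and spacing")
    spacing = np.array(img.spacing_mm)
    if np.allclose(spacing, target_mm):
        return (
            ImageVolume(img.values.copy(), (target_mm,) * 3, img.origin_mm),
            ROIMask(mask.values.copy(), (target_mm,) * 3, mask.origin_mm),
        )
    new_shape = np.maximum(np.ceil(np.array(img.shape) * spacing / target_mm), 1).astype(int)
    # voxel-centre coordinate of new voxel j along an axis, in old index units
    coords = np.meshgrid(
        *[np.arange(n) * target_mm / s for n, s in zip(new_shape, spacing)], indexing="ij"
    )
    new_values = ndimage.map_coordinates(img.values, coords, order=1, mode="nearest")
    new_mask = ndimage.map_coordinates(mask.values.astype(np.uint8), coords, order=0, mode="nearest")
    out_mask = ROIMask(new_mask, (target_mm,) * 3, mask.origin_mm)
    if mask.volume_mm3 >= target_mm**3 and out_mask.n_voxels == 0:
        raise DegenerateROIError("ROI became empty after resampling")
    return ImageVolume(new_values, (target_mm,) * 3, img.origin_mm), out_mask


# ---------------------------------------------------------------------------
# Intensity normalization (ROI-restricted)
# ---------------------------------------------------------------------------

def normalize_minmax(img: ImageVolume, mask: ROIMask) -> ImageVolume:
    """Map ROI intensities to [0, 1] using the ROI min/max; 0 outside the ROI."""
    roi = mask.values
    if not roi.any():
        raise DegenerateROIError("empty ROI")
    v = img.values[roi]
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        raise DegenerateROIError("constant ROI: min-max normalization undefined")
    out = np.zeros_like(img.values)
    out[roi] = (img.values[roi] - lo) / (hi - lo)
    return ImageVolume(out, img.spacing_mm, img.origin_mm)


def normalize_zscore(img: ImageVolume, mask: ROIMask) -> ImageVolume:
    """Standardize ROI intensities to mean 0, population SD 1; 0 outside the ROI."""
    roi = mask.values
    if not roi.any():
        raise DegenerateROIError("empty ROI")
    v = img.values[roi]
    mu = float(v.mean())
    sigma = float(v.std())  # population SD
    if sigma == 0.0:
        raise DegenerateROIError("constant ROI: z-score normalization undefined")
    out = np.zeros_like(img.values)
    out[roi] = (img.values[roi] - mu) / sigma
    return ImageVolume(out, img.spacing_mm, img.origin_mm)


# ---------------------------------------------------------------------------
# Gray-level discretization
# ---------------------------------------------------------------------------

def discretize(img: ImageVolume, mask: ROIMask, n_levels: int = 32) -> DiscretizedVolume:
    """Equal-width binning of ROI intensities into ``n_levels`` gray levels.

    level = min(floor((v - min) / (max - min) * Ng) + 1, Ng).  A constant ROI
    yields all voxels at level 1 with ``degenerate=True``.
    """
    if n_levels < 2:
        raise ValueError(f"n_levels must be >= 2, got {n_levels}")
    roi = mask.values
    if not roi.any():
        raise DegenerateROIError("empty ROI")
    v = img.values[roi]
    lo, hi = float(v.min()), float(v.max())
    labels = np.zeros(img.shape, dtype=np.int32)
    if hi == lo:
        labels[roi] = 1
        return DiscretizedVolume(labels, n_levels, img.spacing_mm, degenerate=True)
    lv = np.floor((v - lo) / (hi - lo) * n_levels).astype(np.int32) + 1
    labels[roi] = np.minimum(lv, n_levels)
    return DiscretizedVolume(labels, n_levels, img.spacing_mm)
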