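"""Per-patient radiomic feature vectors.

``extract_all`` runs the full chain on one image/mask pair: isotropic
resampling, single-level undecimated wavelet bank, per-band ROI-restricted
intensity normalization (min–max or z-score), per-band gray-level
discretization, then histogram + texture features per band and global shape
features.  Band-dependent features are named ``<band><FeatureName>`` (band
``ROI`` is the unfiltered image), matching the usual radiomics naming, e.g.
``HHHRLV`` or ``LLHMean``; shape features carry bare names
(``Max3Ddiameter``, ``SpheDisproportion``, ...).

The feature registry makes the composition of the feature set explicit and
auditable: it lists which per-band statistics and which shape statistics are
computed, plus the discretization depth and GLCM distance.  ``ROIEnergy`` is
bound to the sum of squared ROI intensities.
"""

from __future__ import annotations

import json

import numpy as np
from scipy.spatial.distance import pdist
from skimage import measure

from . import texture
from .exceptions import DegenerateROIError
from .image import (
    DiscretizedVolume,
    ImageVolume,
    ROIMask,
    discretize,
    normalize_minmax,
    normalize_zscore,
    resample_isotropic,
)
from .wavelets import BAND_CODES, wavelet_decompose

__all__ = [
    "DEFAULT_REGISTRY",
    "load_registry",
    "save_registry",
    "shape_features",
    "histogram_features",
    "extract_all",
    "feature_names",
]

DEFAULT_REGISTRY: dict = {
    "band_features": [
        "Mean", "Variance", "Skewness", "Energy",
        "GCorrelation1", "GCorrelation",
        "RLV",
        "LZE", "ZLV", "GLV", "SZLGE", "LGZE", "LZLGE", "LZHGE",
        "Busyness",
    ],
    "shape_features": ["Volume", "SurfaceArea", "Max3Ddiameter", "SpheDisproportion"],
    "n_levels": 32,
    "glcm_distance": 1,
    "wavelet": "coif1",
}

_HISTOGRAM = {"Mean", "Variance", "Skewness", "Energy"}
_GLCM = {"GCorrelation1", "GCorrelation"}
_GLRLM = {"RLV"}
_GLSZM = {"LZE", "ZLV", "GLV", "SZLGE", "LGZE", "LZLGE", "LZHGE"}
_NGTDM = {"Busyness"}


def load_registry(path) -> dict:
    with open(path) as fh:
        reg = json.load(fh)
    merged = dict(DEFAULT_REGISTRY)
    merged.update(reg)
    return merged


def save_registry(registry: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(registry, fh, indent=2)


def feature_names(registry: dict = DEFAULT_REGISTRY) -> list[str]:
    """The fixed, ordered feature name set produced by ``extract_all``."""
    names = [f"{band}{feat}" for band in BAND_CODES for feat in registry["band_features"]]
    names += list(registry["shape_features"])
    return names


# ---------------------------------------------------------------------------
# Shape features
# ---------------------------------------------------------------------------

def shape_features(mask: ROIMask) -> dict[str, float]:
    """Volume (ml), surface area (mm^2), max 3D diameter (mm), sphericity disproportion."""
    if mask.n_voxels == 0:
        raise DegenerateROIError("empty mask")
    volume_mm3 = mask.volume_mm3
    spacing = np.array(mask.spacing_mm)

    # light smoothing before meshing: a level-0.5 surface of the raw binary
    # mask is a voxel staircase that overestimates areas by ~9%
    from scipy import ndimage as _ndi

    padded = np.pad(mask.values.astype(np.float64), 2)
    smooth = _ndi.gaussian_filter(padded, sigma=1.0)
    if smooth.max() <= 0.5:  # tiny regions: fall back to the raw voxel surface
        smooth = padded
    verts, faces, _, _ = measure.marching_cubes(smooth, level=0.5, spacing=tuple(spacing))
    area = float(measure.mesh_surface_area(verts, faces))

    # max pairwise distance between voxel centres; the maximum is attained on
    # the boundary, so restrict to boundary voxels (and their convex hull when
    # large) before the O(n^2) distance computation
    from scipy import ndimage as ndi

    boundary = mask.values & ~ndi.binary_erosion(mask.values)
    pts = np.argwhere(boundary) * spacing
    if len(pts) > 400:
        try:
            from scipy.spatial import ConvexHull

            pts = pts[ConvexHull(pts).vertices]
        except Exception:
            pass
    max_diam = float(pdist(pts).max()) if len(pts) > 1 else 0.0

    r = (3.0 * volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    sphe_dis = area / (4.0 * np.pi * r**2)
    return {
        "Volume": volume_mm3 / 1000.0,
        "SurfaceArea": area,
        "Max3Ddiameter": max_diam,
        "SpheDisproportion": sphe_dis,
    }


# ---------------------------------------------------------------------------
# Histogram features
# ---------------------------------------------------------------------------

def histogram_features(values: np.ndarray) -> tuple[dict[str, float], bool]:
    """First-order statistics of the ROI intensity multiset.

    Returns (features, degenerate_flag); skewness is 0 by convention when the
    SD is 0.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise DegenerateROIError("empty value multiset")
    mu = float(v.mean())
    var = float(v.var())  # population variance
    degenerate = var == 0.0
    skew = 0.0 if degenerate else float(((v - mu) ** 3).mean() / var**1.5)
    return {"Mean": mu, "Variance": var, "Skewness": skew, "Energy": float((v**2).sum())}, degenerate


# ---------------------------------------------------------------------------
# Full extraction
# ---------------------------------------------------------------------------

def _crop_to_roi(d: DiscretizedVolume) -> DiscretizedVolume:
    """Crop labels to the ROI bounding box (texture statistics are unchanged:
    out-of-ROI voxels carry label 0 and never contribute)."""
    idx = np.nonzero(d.labels)
    sl = tuple(slice(int(i.min()), int(i.max()) + 1) for i in idx)
    return DiscretizedVolume(d.labels[sl], d.n_levels, d.spacing_mm, d.degenerate)


def _band_features(d: DiscretizedVolume, wanted: set[str], distance: int) -> dict[str, float]:
    out: dict[str, float] = {}
    if wanted & _GLCM:
        out.update({k: v for k, v in texture.glcm_features(d, distance).items() if k in wanted})
    if wanted & _GLRLM:
        out.update({k: v for k, v in texture.glrlm_features(texture.build_glrlm(d)).items() if k in wanted})
    if wanted & _GLSZM:
        out.update({k: v for k, v in texture.glszm_features(texture.build_glszm(d)).items() if k in wanted})
    if wanted & _NGTDM:
        s, p = texture.build_ngtdm(d)
        out.update({k: v for k, v in texture.ngtdm_features(s, p).items() if k in wanted})
    return out


def extract_all(
    img: ImageVolume,
    mask: ROIMask,
    registry: dict = DEFAULT_REGISTRY,
    normalization: str = "zscore",
    resample: bool = True,
    target_mm: float = 2.0,
) -> tuple[dict[str, float], list[str]]:
    """Extract the full named feature vector for one patient.

    Returns ``(features, flags)``: a name -> finite value mapping whose key
    set is fixed by the registry, and a list of degeneracy flags (band codes
    whose ROI intensities were constant; their texture features take the
    documented conventions).
    """
    if normalization not in ("minmax", "zscore"):
        raise ValueError(f"unknown normalization {normalization!r}")
    if resample:
        img, mask = resample_isotropic(img, mask, target_mm)
    normalize = normalize_minmax if normalization == "minmax" else normalize_zscore

    # restrict to the ROI bounding box plus a margin wider than the wavelet
    # filter support: band values inside the ROI are unchanged, everything
    # outside the ROI is ignored by every feature
    if mask.n_voxels:
        idx = np.nonzero(mask.values)
        margin = 8
        sl = tuple(
            slice(max(int(i.min()) - margin, 0), min(int(i.max()) + 1 + margin, n))
            for i, n in zip(idx, mask.shape)
        )
        img = ImageVolume(img.values[sl], img.spacing_mm, img.origin_mm)
        mask = ROIMask(mask.values[sl], mask.spacing_mm, mask.origin_mm)

    bank = wavelet_decompose(img, wavelet=registry.get("wavelet", "coif1"))
    wanted = set(registry["band_features"])
    n_levels = int(registry.get("n_levels", 32))
    distance = int(registry.get("glcm_distance", 1))

    features: dict[str, float] = {}
    flags: list[str] = []
    roi = mask.values
    # reference scale for degeneracy: a band whose ROI spread is numerically
    # zero relative to the input contrast carries no signal, only roundoff
    ref = np.ptp(img.values[roi])
    tiny = 1e-12 * max(ref, 1e-30)
    for band in BAND_CODES:
        vol = bank[band]
        degenerate = float(vol.values[roi].std()) <= tiny
        if not degenerate:
            try:
                norm = normalize(vol, mask)
            except DegenerateROIError:
                degenerate = True
        if degenerate:
            norm = ImageVolume(np.zeros(vol.shape), vol.spacing_mm, vol.origin_mm)
        hist, hist_degen = histogram_features(norm.values[roi])
        degenerate = degenerate or hist_degen
        if degenerate:
            flags.append(band)
        for k in _HISTOGRAM & wanted:
            features[f"{band}{k}"] = hist[k]
        d = _crop_to_roi(discretize(norm, mask, n_levels))
        for k, v in _band_features(d, wanted, distance).items():
            features[f"{band}{k}"] = v

    if registry["shape_features"]:
        sf = shape_features(mask)
        for k in registry["shape_features"]:
            features[k] = sf[k]

    order = feature_names(registry)
    return {k: features[k] for k in order}, flags
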