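"""3D gray-level texture matrices and their scalar features.

All four matrix families operate on a :class:`~ofrad.image.DiscretizedVolume`
(labels 1..Ng inside the ROI, 0 outside) and follow the conventions of the
image-biomarker standardisation lineage:

* GLCM — co-occurrences over the 13 unique 3D directions at a given distance,
  restricted to voxel pairs both inside the ROI, symmetrized.  Features can be
  computed from the direction-merged matrix (``GCorrelation1``) or averaged
  over per-direction matrices (``GCorrelation``).
* GLRLM — maximal runs of equal gray level along each of the 13 directions,
  pooled into one level x run-length table.
* GLSZM — 26-connected zones of equal gray level.
* NGTDM — absolute difference between a voxel's level and the mean level of
  its 26-neighbourhood (within the ROI).

Degenerate (single-gray-level) ROIs take explicit conventions: GLCM
correlation 0, NGTDM busyness 0.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .image import DiscretizedVolume

__all__ = [
    "DIRECTIONS_13",
    "build_glcm",
    "build_glcm_per_direction",
    "glcm_correlation",
    "glcm_features",
    "build_glrlm",
    "glrlm_features",
    "build_glszm",
    "glszm_features",
    "build_ngtdm",
    "ngtdm_features",
]

# one representative per +/- direction pair of the 26-neighbourhood
DIRECTIONS_13 = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)


def _offset_slices(shape, offset):
    """Slice pairs (a, b) such that arr[a] and arr[b] are shifted by ``offset``."""
    sa, sb = [], []
    for n, d in zip(shape, offset):
        if d >= 0:
            sa.append(slice(0, n - d))
            sb.append(slice(d, n))
        else:
            sa.append(slice(-d, n))
            sb.append(slice(0, n + d))
    return tuple(sa), tuple(sb)


def _glcm_one_direction(labels: np.ndarray, n_levels: int, offset) -> np.ndarray:
    sa, sb = _offset_slices(labels.shape, offset)
    a = labels[sa].ravel()
    b = labels[sb].ravel()
    valid = (a > 0) & (b > 0)
    a, b = a[valid] - 1, b[valid] - 1
    m = np.bincount(a * n_levels + b, minlength=n_levels * n_levels).reshape(n_levels, n_levels)
    return (m + m.T).astype(np.float64)


def build_glcm(d: DiscretizedVolume, distance: int = 1) -> np.ndarray:
    """Direction-merged, symmetrized, normalized co-occurrence matrix (sums to 1)."""
    total = np.zeros((d.n_levels, d.n_levels))
    for off in DIRECTIONS_13:
        total += _glcm_one_direction(d.labels, d.n_levels, tuple(distance * o for o in off))
    s = total.sum()
    return total / s if s > 0 else total


def build_glcm_per_direction(d: DiscretizedVolume, distance: int = 1) -> list[np.ndarray]:
    """One symmetrized normalized matrix per direction (empty directions stay zero)."""
    out = []
    for off in DIRECTIONS_13:
        m = _glcm_one_direction(d.labels, d.n_levels, tuple(distance * o for o in off))
        s = m.sum()
        out.append(m / s if s > 0 else m)
    return out


def glcm_correlation(p: np.ndarray) -> float:
    """Correlation of the co-occurring levels; 0 by convention if degenerate."""
    if p.sum() == 0:
        return 0.0
    levels = np.arange(1, p.shape[0] + 1, dtype=np.float64)
    px = p.sum(axis=1)
    mu = float(levels @ px)
    var = float(((levels - mu) ** 2) @ px)
    if var <= 0:
        return 0.0
    cov = float(levels @ p @ levels - mu * mu)
    return cov / var


def glcm_features(d: DiscretizedVolume, distance: int = 1) -> dict[str, float]:
    merged = build_glcm(d, distance)
    per_dir = build_glcm_per_direction(d, distance)
    nonempty = [p for p in per_dir if p.sum() > 0]
    per_dir_corr = float(np.mean([glcm_correlation(p) for p in nonempty])) if nonempty else 0.0
    return {"GCorrelation1": glcm_correlation(merged), "GCorrelation": per_dir_corr}


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def _runs_one_direction(labels: np.ndarray, offset) -> tuple[np.ndarray, np.ndarray]:
    """(levels, lengths) of all maximal runs along ``offset`` inside the ROI."""
    shape = labels.shape
    roi = labels > 0
    # a voxel starts a run if its predecessor (voxel - offset) is outside the
    # volume/ROI or carries a different label
    prev = np.zeros(shape, dtype=labels.dtype)
    sa, sb = _offset_slices(shape, offset)
    # labels[sa] shifted by +offset lands at labels[sb]
    prev[sb] = labels[sa]
    starts = roi & (prev != labels)
    xs, ys, zs = np.nonzero(starts)
    run_levels = labels[xs, ys, zs]
    lengths = np.ones(len(xs), dtype=np.int64)
    active = np.arange(len(xs))
    cx, cy, cz = xs.copy(), ys.copy(), zs.copy()
    dx, dy, dz = offset
    while active.size:
        cx[active] += dx
        cy[active] += dy
        cz[active] += dz
        inb = (
            (cx[active] >= 0) & (cx[active] < shape[0])
            & (cy[active] >= 0) & (cy[active] < shape[1])
            & (cz[active] >= 0) & (cz[active] < shape[2])
        )
        active = active[inb]
        if not active.size:
            break
        same = labels[cx[active], cy[active], cz[active]] == run_levels[active]
        active = active[same]
        lengths[active] += 1
    return run_levels, lengths


def build_glrlm(d: DiscretizedVolume) -> np.ndarray:
    """Level x run-length count matrix pooled over the 13 directions.

    Entry ``[i-1, j-1]`` counts runs of level ``i`` and length ``j``.
    """
    all_levels, all_lengths = [], []
    for off in DIRECTIONS_13:
        lv, ln = _runs_one_direction(d.labels, off)
        all_levels.append(lv)
        all_lengths.append(ln)
    levels = np.concatenate(all_levels)
    lengths = np.concatenate(all_lengths)
    if len(levels) == 0:
        return np.zeros((d.n_levels, 1))
    rmax = int(lengths.max())
    m = np.zeros((d.n_levels, rmax))
    np.add.at(m, (levels - 1, lengths - 1), 1.0)
    return m


def glrlm_features(glrlm: np.ndarray) -> dict[str, float]:
    total = glrlm.sum()
    if total == 0:
        return {"RLV": 0.0}
    p = glrlm / total
    j = np.arange(1, glrlm.shape[1] + 1, dtype=np.float64)
    pj = p.sum(axis=0)
    mu_j = float(j @ pj)
    rlv = float(((j - mu_j) ** 2) @ pj)
    return {"RLV": rlv}


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def build_glszm(d: DiscretizedVolume) -> np.ndarray:
    """Level x zone-size count matrix over 26-connected equal-level zones."""
    sizes_per_level: dict[int, np.ndarray] = {}
    smax = 1
    for level in np.unique(d.labels[d.labels > 0]):
        lab, n = ndimage.label(d.labels == level, structure=_STRUCT_26)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        sizes_per_level[int(level)] = sizes
        smax = max(smax, int(sizes.max()))
    m = np.zeros((d.n_levels, smax))
    for level, sizes in sizes_per_level.items():
        np.add.at(m, (level - 1, sizes - 1), 1.0)
    return m


def glszm_features(glszm: np.ndarray) -> dict[str, float]:
    names = ("LZE", "ZLV", "GLV", "SZLGE", "LGZE", "LZLGE", "LZHGE")
    total = glszm.sum()
    if total == 0:
        return {k: 0.0 for k in names}
    p = glszm / total
    i = np.arange(1, glszm.shape[0] + 1, dtype=np.float64)[:, None]
    s = np.arange(1, glszm.shape[1] + 1, dtype=np.float64)[None, :]
    mu_s = float((p * s).sum())
    mu_i = float((p * i).sum())
    return {
        "LZE": float((p * s**2).sum()),
        "ZLV": float((p * (s - mu_s) ** 2).sum()),
        "GLV": float((p * (i - mu_i) ** 2).sum()),
        "SZLGE": float((p / (i**2 * s**2)).sum()),
        "LGZE": float((p / i**2).sum()),
        "LZLGE": float((p * s**2 / i**2).sum()),
        "LZHGE": float((p * s**2 * i**2).sum()),
    }


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def build_ngtdm(d: DiscretizedVolume) -> tuple[np.ndarray, np.ndarray]:
    """Per-level coarseness sums ``s_i`` and level probabilities ``p_i``.

    ``s_i`` sums |level - mean 26-neighbourhood level| over ROI voxels of level
    ``i``; neighbourhood means use only in-ROI neighbours.  Returns arrays of
    length Ng (index i-1).
    """
    roi = d.roi
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nb_sum = ndimage.correlate(d.labels.astype(np.float64) * roi, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.correlate(roi.astype(np.float64), kernel, mode="constant", cval=0.0)
    valid = roi & (nb_cnt > 0)
    diff = np.zeros(d.labels.shape)
    diff[valid] = np.abs(d.labels[valid] - nb_sum[valid] / nb_cnt[valid])
    s = np.zeros(d.n_levels)
    np.add.at(s, d.labels[valid] - 1, diff[valid])
    counts = np.bincount(d.labels[roi].ravel() - 1, minlength=d.n_levels).astype(np.float64)
    n = counts.sum()
    p = counts / n if n > 0 else counts
    return s, p


def ngtdm_features(s: np.ndarray, p: np.ndarray) -> dict[str, float]:
    occur = p > 0
    num = float((p * s).sum())
    i = np.arange(1, len(p) + 1, dtype=np.float64)
    ip = (i * p)[occur]
    denom = float(np.abs(ip[:, None] - ip[None, :]).sum())
    busyness = num / denom if denom > 0 else 0.0
    return {"Busyness": busyness}
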