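"""Single-level undecimated 3D wavelet bank.

The eight sub-bands of a separable single-level stationary (a trous) wavelet
transform, plus the unfiltered image under band code ``ROI``, all on the
original voxel grid so a single tumour mask applies to every band.  Band codes
are three letters, one per array axis in order (x, y, z): ``L`` = low-pass,
``H`` = high-pass — e.g. ``HLL`` filters high-pass along x and low-pass along
y and z.

The transform correlates each axis with the analysis filters of an orthonormal
wavelet (default ``coif1``) under symmetric (mirror) boundary extension: the
volume is mirror-padded and filtered circularly.  For a conjugate-quadrature
filter pair ``|H|^2 + |G|^2 = 2`` at every frequency, so convolving each
sub-band back with its own filter, summing, and halving per axis recovers the
input exactly — :func:`reconstruct` implements that inverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pywt
from scipy import ndimage

from .exceptions import FormatError
from .image import ImageVolume

__all__ = ["DETAIL_BANDS", "BAND_CODES", "WaveletBank", "wavelet_decompose", "reconstruct"]

DETAIL_BANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")
BAND_CODES = ("ROI",) + DETAIL_BANDS


@dataclass
class WaveletBank:
    """Mapping band code -> ImageVolume, all sharing the input grid."""

    bands: dict[str, ImageVolume]
    wavelet: str = "coif1"
    _padded: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _pad: int = 0

    def __getitem__(self, code: str) -> ImageVolume:
        return self.bands[code]

    def __len__(self) -> int:
        return len(self.bands)

    def keys(self):
        return self.bands.keys()


@lru_cache(maxsize=8)
def _filters(wavelet: str) -> tuple[np.ndarray, np.ndarray, int]:
    """(dec_lo, dec_hi, roll) where ``roll`` realigns analysis+synthesis to
    the identity for this filter length (calibrated on a 1D impulse)."""
    w = pywt.Wavelet(wavelet)
    lo = np.asarray(w.dec_lo)
    hi = np.asarray(w.dec_hi)
    n = 4 * len(lo)
    impulse = np.zeros(n)
    impulse[n // 2] = 1.0
    rec = np.zeros(n)
    for f in (lo, hi):
        band = ndimage.correlate1d(impulse, f, mode="wrap")
        rec += ndimage.convolve1d(band, f, mode="wrap")
    rec /= 2.0
    shift = int(np.argmax(np.abs(rec))) - n // 2
    return lo, hi, shift


def wavelet_decompose(img: ImageVolume, wavelet: str = "coif1", pad: int | None = None) -> WaveletBank:
    """Decompose ``img`` into the 9-entry undecimated wavelet bank."""
    lo, hi, _ = _filters(wavelet)
    L = len(lo)
    if min(img.shape) < L:
        raise FormatError(
            f"image shape {img.shape} smaller than the {wavelet} filter support ({L})"
        )
    if pad is None:
        pad = L
    x = np.pad(img.values, pad, mode="symmetric")
    # separable analysis tree: 2 -> 4 -> 8 filtered volumes
    current: dict[str, np.ndarray] = {"": x}
    for axis in range(3):
        nxt: dict[str, np.ndarray] = {}
        for code, arr in current.items():
            nxt[code + "L"] = ndimage.correlate1d(arr, lo, axis=axis, mode="wrap")
            nxt[code + "H"] = ndimage.correlate1d(arr, hi, axis=axis, mode="wrap")
        current = nxt
    crop = tuple(slice(pad, pad + n) for n in img.shape)
    bands: dict[str, ImageVolume] = {
        "ROI": ImageVolume(img.values.copy(), img.spacing_mm, img.origin_mm)
    }
    for code in DETAIL_BANDS:
        bands[code] = ImageVolume(current[code][crop], img.spacing_mm, img.origin_mm)
    return WaveletBank(bands=bands, wavelet=wavelet, _padded=current, _pad=pad)


def reconstruct(bank: WaveletBank) -> np.ndarray:
    """Invert the bank: synthesis-filter each sub-band, sum, halve per axis.

    Returns an array on the original grid equal to the input to numerical
    precision (the stationary transform is exactly invertible).
    """
    if not bank._padded:
        raise ValueError("bank does not carry the padded sub-bands needed for reconstruction")
    lo, hi, shift = _filters(bank.wavelet)
    acc = None
    for code, arr in bank._padded.items():
        b = arr
        for axis, letter in enumerate(code):
            f = lo if letter == "L" else hi
            b = ndimage.convolve1d(b, f, axis=axis, mode="wrap")
        acc = b if acc is None else acc + b
    rec = acc / 8.0
    if shift:
        rec = np.roll(rec, (-shift, -shift, -shift), axis=(0, 1, 2))
    pad = bank._pad
    shape = bank.bands["ROI"].shape
    crop = tuple(slice(pad, pad + n) for n in shape)
    return rec[crop]
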