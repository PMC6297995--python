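"""The five per-image features used as VLT predictors.

All features are computed on the window-mapped 8-bit display raster — the
intensities under which the observer thresholds are measured — not on raw
HU. The five features:

* ``image_sd`` — population standard deviation of display intensities.
* ``image_entropy`` — Shannon entropy (bits) of the 256-bin histogram.
* ``percentage_lf`` — share (%) of AC energy in the low-frequency corner
  (index sum u+v <= 2) of the blockwise 8x8 DCT.
* ``variation_hf`` — RMS of the diagonal-detail (HH) subband of a
  one-level Haar transform; the HH subband has zero mean by construction,
  so this is its standard deviation about zero.
* ``visual_complexity`` — losslessly JPEG2000-encoded bytes divided by raw
  display bytes, a compressibility-based complexity proxy in (0, ~1.1].

Each feature sits behind its own function so an alternative definition can
be swapped in without touching the regression code.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pywt
import scipy.fft

from . import codec_jp2k
from .dicom_io import CTImage, WindowSetting, apply_window, default_window

__all__ = [
    "FeatureVector",
    "image_sd",
    "image_entropy",
    "percentage_lf",
    "variation_hf",
    "visual_complexity",
    "compute_feature_vector",
    "FEATURE_NAMES",
]

FEATURE_NAMES = (
    "image_sd",
    "image_entropy",
    "percentage_lf",
    "variation_hf",
    "visual_complexity",
)


@dataclass(frozen=True)
class FeatureVector:
    image_sd: float
    image_entropy: float
    percentage_lf: float
    variation_hf: float
    visual_complexity: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _check(display: np.ndarray) -> np.ndarray:
    arr = np.asarray(display)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("display raster must be a non-empty 2-D array")
    return arr


def image_sd(display: np.ndarray) -> float:
    """Population standard deviation of display intensities."""
    return float(np.std(_check(display).astype(np.float64)))


def image_entropy(display: np.ndarray) -> float:
    """Shannon entropy (bits) of the 256-bin intensity histogram."""
    arr = _check(display)
    counts = np.bincount(
        np.clip(arr.astype(np.int64).ravel(), 0, 255), minlength=256
    )
    p = counts[counts > 0] / arr.size
    return float(-np.sum(p * np.log2(p)))


# AC coefficients of an 8x8 DCT block with index sum u+v <= 2
_LF_MASK = np.zeros((8, 8), dtype=bool)
for _u in range(8):
    for _v in range(8):
        if 0 < _u + _v <= 2:
            _LF_MASK[_u, _v] = True


def percentage_lf(display: np.ndarray) -> float:
    """Percentage of blockwise 8x8 DCT AC energy in the low-frequency set.

    Low-frequency set: AC coefficients with index sum u+v <= 2. A raster
    with zero AC energy (e.g. constant) returns 0 by convention. Rasters
    are trimmed to whole 8x8 blocks.
    """
    arr = _check(display).astype(np.float64)
    h, w = arr.shape
    if h < 8 or w < 8:
        raise ValueError("raster must be at least 8x8 for the blockwise DCT")
    hb, wb = h // 8, w // 8
    blocks = arr[: hb * 8, : wb * 8].reshape(hb, 8, wb, 8).transpose(0, 2, 1, 3)
    coef = scipy.fft.dctn(blocks, type=2, norm="ortho", axes=(-2, -1))
    energy = coef**2
    ac_total = float(energy.sum() - energy[..., 0, 0].sum())
    if ac_total == 0.0:
        return 0.0
    lf = float(energy[..., _LF_MASK].sum())
    return 100.0 * lf / ac_total


def variation_hf(display: np.ndarray, wavelet: str = "haar") -> float:
    """RMS of the diagonal-detail (HH) subband of a one-level wavelet
    transform (standard deviation about the subband's zero mean)."""
    arr = _check(display)
    h, w = arr.shape
    if h % 2 or w % 2 or h < 2 or w < 2:
        raise ValueError("raster must have even dimensions >= 2 (pad first)")
    _, (_, _, hh) = pywt.dwt2(arr.astype(np.float64), wavelet)
    return float(np.sqrt(np.mean(hh**2)))


def visual_complexity(display: np.ndarray) -> float:
    """Lossless JPEG2000 bytes divided by raw display bytes."""
    arr = _check(display)
    code = codec_jp2k.encode_lossless(arr.astype(np.uint8))
    return len(code) / arr.size


def compute_feature_vector(
    image: CTImage, window: WindowSetting | None = None
) -> FeatureVector:
    """All five features on one window-mapped raster (deterministic).

    The window defaults to the clinical window for the image's body part.
    """
    if window is None:
        window = default_window(image.meta.body_part)
    display = apply_window(image, window)
    return FeatureVector(
        image_sd=image_sd(display),
        image_entropy=image_entropy(display),
        percentage_lf=percentage_lf(display),
        variation_hf=variation_hf(display),
        visual_complexity=visual_complexity(display),
    )
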