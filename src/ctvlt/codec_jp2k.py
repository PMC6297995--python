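"""Irreversible JPEG2000 compression of CT rasters at a target ratio.

Compression ratio (CR) is defined on uncompressed *pixel-data* bytes, with
the numerator fixed at ``rows * cols * 2`` (a 16-bit container) regardless
of stored bit depth, so that ratios are comparable across images. HU
pixels are shifted to an unsigned 12-bit range (HU + 1024) before
encoding; the shift is lossless and inverted on decode.

Encoding uses the 9/7 irreversible wavelet with a single tile and a single
quality layer per target rate (OpenJPEG via Pillow). Rate control
quantizes to packet boundaries, so the achieved CR is only required to lie
within ±5% of the target; the encoder retries with a proportionally
corrected rate parameter a few times before giving up.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from PIL import Image

from .dicom_io import CTImage

__all__ = [
    "CompressedImage",
    "CodecError",
    "RateControlError",
    "compress_to_ratio",
    "decode",
    "encode_lossless",
    "distortion_vs_cr_curve",
    "RAW_BYTES_PER_PIXEL",
]

RAW_BYTES_PER_PIXEL = 2
HU_SHIFT = 1024

#: encoder configuration, recorded for reproducibility
CODEC_CONFIG = {
    "wavelet": "9/7 irreversible",
    "levels": 6,          # num_resolutions (5 decompositions)
    "tiles": 1,
    "quality_layers": 1,
    "tolerance_pct": 5.0,
    "max_attempts": 4,
}


class CodecError(RuntimeError):
    """JPEG2000 encoding or decoding failed."""


class RateControlError(CodecError):
    """Rate control could not reach the target CR within tolerance."""

    def __init__(self, target_cr: float, achieved_cr: float):
        self.target_cr = target_cr
        self.achieved_cr = achieved_cr
        super().__init__(
            f"rate control missed target CR {target_cr:g}: achieved {achieved_cr:.3f}"
        )


@dataclass
class CompressedImage:
    """A JPEG2000 codestream plus its decoded raster and CR accounting."""

    codestream: bytes
    target_cr: float
    achieved_cr: float
    decoded: np.ndarray  # HU raster, same shape as the source
    #: True when the target CR lies below the codec's quality floor: the
    #: most faithful encoding is already smaller than requested, so the
    #: achieved CR exceeds the target while distortion is minimal.
    quality_floor: bool = False


def _encode_once(u12: np.ndarray, rate: float) -> bytes:
    buf = io.BytesIO()
    Image.fromarray(u12).save(
        buf,
        format="JPEG2000",
        irreversible=True,
        quality_mode="rates",
        quality_layers=[float(rate)],
        num_resolutions=CODEC_CONFIG["levels"],
    )
    return buf.getvalue()


def _decode_bytes(codestream: bytes, expect_shape=None) -> np.ndarray:
    try:
        with Image.open(io.BytesIO(codestream)) as im:
            arr = np.asarray(im)
    except Exception as exc:  # PIL raises OSError/SyntaxError on corrupt streams
        raise CodecError(f"cannot decode JPEG2000 codestream: {exc}") from exc
    if arr.ndim != 2:
        raise CodecError(f"decoded raster has unexpected shape {arr.shape}")
    if expect_shape is not None and arr.shape != tuple(expect_shape):
        raise CodecError(
            f"decoded shape {arr.shape} does not match source {tuple(expect_shape)}"
        )
    return arr.astype(np.int32) - HU_SHIFT


def compress_to_ratio(
    image: CTImage,
    target_cr: float,
    tolerance_pct: float | None = None,
) -> CompressedImage:
    """Compress a CT image so the achieved CR is within ±5% of target.

    Deterministic for a fixed input and target. Raises
    :class:`RateControlError` (carrying the achieved value) if the
    tolerance cannot be met.
    """
    if not target_cr > 1:
        raise ValueError(f"target_cr must be > 1, got {target_cr}")
    tol = CODEC_CONFIG["tolerance_pct"] if tolerance_pct is None else tolerance_pct

    u12 = (image.pixels.astype(np.int32) + HU_SHIFT).astype(np.uint16)
    raw_bytes = image.rows * image.cols * RAW_BYTES_PER_PIXEL

    rate = float(target_cr)
    best = None
    floor = False
    for _ in range(CODEC_CONFIG["max_attempts"]):
        codestream = _encode_once(u12, rate)
        achieved = raw_bytes / len(codestream)
        if best is None or abs(achieved - target_cr) < abs(best[1] - target_cr):
            best = (codestream, achieved)
        if abs(achieved - target_cr) <= tol / 100.0 * target_cr:
            break
        if achieved > target_cr:
            # rate control enforces the byte budget as a ceiling, so an
            # overshoot means the most faithful encoding is already
            # smaller than requested: the target sits below the codec's
            # quality floor for this image
            floor = True
            break
        # undershoot (container overhead): ask for a slightly higher rate
        rate *= target_cr / achieved
    codestream, achieved = best
    if not floor and abs(achieved - target_cr) > tol / 100.0 * target_cr:
        raise RateControlError(target_cr, achieved)

    decoded = np.clip(
        _decode_bytes(codestream, expect_shape=image.pixels.shape),
        -HU_SHIFT,
        3071,
    ).astype(np.int16)
    return CompressedImage(
        codestream=codestream,
        target_cr=float(target_cr),
        achieved_cr=achieved,
        decoded=decoded,
        quality_floor=floor,
    )


def decode(compressed: CompressedImage) -> np.ndarray:
    """Decode a codestream back to an HU raster (deterministic)."""
    arr = _decode_bytes(compressed.codestream)
    return np.clip(arr, -HU_SHIFT, 3071).astype(np.int16)


def encode_lossless(raster: np.ndarray) -> bytes:
    """Losslessly JPEG2000-encode a raster; used by the complexity feature."""
    arr = np.asarray(raster)
    if arr.dtype not in (np.uint8, np.uint16):
        raise ValueError("lossless encoding expects a uint8 or uint16 raster")
    buf = io.BytesIO()
    try:
        Image.fromarray(arr).save(buf, format="JPEG2000", irreversible=False)
    except Exception as exc:
        raise CodecError(f"lossless JPEG2000 encoding failed: {exc}") from exc
    return buf.getvalue()


def distortion_vs_cr_curve(
    image: CTImage, crs: list[float]
) -> list[tuple[float, float]]:
    """Mean squared HU error of the decoded image at each CR.

    ``crs`` must be strictly increasing and all > 1. MSE is non-decreasing
    in CR up to rate-control jitter (~2%).
    """
    if len(crs) == 0:
        raise ValueError("crs must be non-empty")
    arr = np.asarray(crs, dtype=float)
    if np.any(arr <= 1) or np.any(np.diff(arr) <= 0):
        raise ValueError("crs must be strictly increasing and all > 1")
    src = image.pixels.astype(np.float64)
    out = []
    for cr in arr:
        comp = compress_to_ratio(image, float(cr))
        mse = float(np.mean((comp.decoded.astype(np.float64) - src) ** 2))
        out.append((float(cr), mse))
    return out
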