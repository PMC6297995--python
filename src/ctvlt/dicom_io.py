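"""Single-slice CT DICOM input/output and display windowing.

A :class:`CTImage` is the unit of analysis throughout the package: a 2-D
Hounsfield-unit raster plus the four acquisition covariates that enter the
VLT regression model (effective mAs, section thickness, field of view,
reconstruction filter), the body part, and a low-dose flag.

Header covariates are read strictly from the tags that carry them on the
scanners this toolkit targets:

===================  ============================  =======================
covariate            tag                           keyword
===================  ============================  =======================
effective mAs        (0018,9332)                   ExposureInmAs
section thickness    (0018,0050)                   SliceThickness
field of view        (0018,0090)                   DataCollectionDiameter
reconstruction       (0018,9320)                   ImageFilter
===================  ============================  =======================

There is deliberately no fallback to (0018,1151)/(0018,1152) for the tube
current: a silent fallback would change the regression covariate.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

__all__ = [
    "BODY_PARTS",
    "CTImage",
    "AcquisitionMeta",
    "WindowSetting",
    "MissingTagError",
    "DEFAULT_FILTER_MAP",
    "read_ct_image",
    "write_phantom_dicom",
    "apply_window",
    "window_hu",
    "default_window",
    "estimate_effective_dose",
]

HU_MIN = -1024
HU_MAX = 3071

RECON_FILTERS = ("soft-tissue", "medium-sharp")
BODY_PARTS = ("abdomen", "chest")

#: Mapping from DICOM Image Filter strings (0018,9320) to the two-level
#: reconstruction-filter factor. Unmapped strings raise; extend via the
#: ``filter_map`` argument of :func:`read_ct_image` for other scanners.
DEFAULT_FILTER_MAP: dict[str, str] = {
    "SOFT_TISSUE": "soft-tissue",
    "SOFT-TISSUE": "soft-tissue",
    "SOFT": "soft-tissue",
    "STANDARD": "soft-tissue",
    "B": "soft-tissue",
    "MEDIUM_SHARP": "medium-sharp",
    "MEDIUM-SHARP": "medium-sharp",
    "SHARP": "medium-sharp",
    "LUNG": "medium-sharp",
    "YC": "medium-sharp",
}

#: Conversion factors from dose-length product (mGy·cm) to effective dose
#: (mSv), per body region.
DOSE_CONVERSION = {"abdomen": 0.017, "chest": 0.019}

_LOW_DOSE_COMMENT = "LOW_DOSE"


class MissingTagError(ValueError):
    """A required DICOM header tag is absent."""


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition covariates of one CT section."""

    effective_mas: float
    section_thickness_mm: float
    fov_mm: float
    recon_filter: str
    body_part: str
    low_dose: bool = False

    def __post_init__(self) -> None:
        for name in ("effective_mas", "section_thickness_mm", "fov_mm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.recon_filter not in RECON_FILTERS:
            raise ValueError(
                f"recon_filter must be one of {RECON_FILTERS}, got {self.recon_filter!r}"
            )
        if self.body_part not in BODY_PARTS:
            raise ValueError(
                f"body_part must be one of {BODY_PARTS}, got {self.body_part!r}"
            )


@dataclass
class CTImage:
    """A single transverse CT section in Hounsfield units."""

    pixels: np.ndarray
    meta: AcquisitionMeta
    image_id: str = ""
    study_conformant: bool = field(init=False, default=True)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D raster")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError("pixels must be an integer HU raster")
        if px.min() < HU_MIN or px.max() > HU_MAX:
            raise ValueError(f"HU values must lie in [{HU_MIN}, {HU_MAX}]")
        self.pixels = px
        # 512x512 is the study-conformant matrix; other sizes are accepted
        # but flagged so downstream consumers can tell.
        self.study_conformant = px.shape == (512, 512)

    @property
    def rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def cols(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class WindowSetting:
    """Linear display window (level/width in HU)."""

    level: float
    width: float

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError("window width must be > 0")


#: Clinical default windows: abdomen 20/400 HU, chest (lung) -600/1500 HU.
DEFAULT_WINDOWS = {
    "abdomen": WindowSetting(level=20.0, width=400.0),
    "chest": WindowSetting(level=-600.0, width=1500.0),
}


def default_window(body_part: str) -> WindowSetting:
    """Return the default display window for a body part."""
    try:
        return DEFAULT_WINDOWS[body_part]
    except KeyError:
        raise ValueError(
            f"no default window for body part {body_part!r}; known: {BODY_PARTS}"
        ) from None


def window_hu(hu: np.ndarray, window: WindowSetting) -> np.ndarray:
    """Map an HU array to an 8-bit display raster through a linear window.

    HU at or below ``level - width/2`` map to 0, at or above
    ``level + width/2`` to 255. The midpoint (HU == level) rounds half-up
    to 128.
    """
    if not window.width > 0:
        raise ValueError("window width must be > 0")
    lo = window.level - window.width / 2.0
    frac = np.clip((np.asarray(hu, dtype=np.float64) - lo) / window.width, 0.0, 1.0)
    return np.floor(frac * 255.0 + 0.5).astype(np.uint8)


def apply_window(image: CTImage, window: WindowSetting) -> np.ndarray:
    """Window-map a :class:`CTImage` to its 8-bit display raster."""
    return window_hu(image.pixels, window)


def estimate_effective_dose(dlp: float, body_part: str) -> float:
    """Effective dose (mSv) from a dose-length product (mGy·cm).

    Uses the body-region conversion factors 0.017 (abdomen) and
    0.019 (chest) mSv/(mGy·cm).
    """
    if dlp < 0:
        raise ValueError("dose-length product must be non-negative")
    try:
        return dlp * DOSE_CONVERSION[body_part]
    except KeyError:
        raise ValueError(
            f"no dose conversion factor for body part {body_part!r}"
        ) from None


def _require(ds: pydicom.Dataset, tag: int, name: str):
    if tag not in ds or ds[tag].value in (None, ""):
        raise MissingTagError(
            f"required tag ({tag >> 16:04X},{tag & 0xFFFF:04X}) {name} is missing"
        )
    return ds[tag].value


def read_ct_image(path, filter_map: dict[str, str] | None = None) -> CTImage:
    """Read a single-slice CT DICOM file into a :class:`CTImage`.

    Stored values are rescaled to HU with the file's rescale slope and
    intercept. All four header covariates must be present; a missing tag
    raises :class:`MissingTagError` naming it — there are no silent
    defaults.
    """
    ds = pydicom.dcmread(str(path))
    if "PixelData" not in ds:
        raise ValueError(f"{path}: DICOM file has no pixel data")

    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    hu = np.rint(ds.pixel_array.astype(np.float64) * slope + intercept)
    hu = np.clip(hu, HU_MIN, HU_MAX).astype(np.int16)

    mas = float(_require(ds, 0x00189332, "Exposure in mAs (effective mAs)"))
    st = float(_require(ds, 0x00180050, "Slice Thickness"))
    fov = float(_require(ds, 0x00180090, "Data Collection Diameter (FOV)"))
    filt_raw = str(_require(ds, 0x00189320, "Image Filter (reconstruction filter)"))

    fmap = DEFAULT_FILTER_MAP if filter_map is None else filter_map
    key = filt_raw.strip().upper()
    if key not in fmap:
        raise ValueError(
            f"unmapped reconstruction filter string {filt_raw!r}; "
            "extend the filter map to read this scanner"
        )

    body_raw = str(getattr(ds, "BodyPartExamined", "")).strip().upper()
    body = {"ABDOMEN": "abdomen", "CHEST": "chest"}.get(body_raw)
    if body is None:
        raise MissingTagError(
            f"Body Part Examined (0018,0015) missing or unsupported: {body_raw!r}"
        )
    low_dose = _LOW_DOSE_COMMENT in str(getattr(ds, "ImageComments", ""))

    meta = AcquisitionMeta(
        effective_mas=mas,
        section_thickness_mm=st,
        fov_mm=fov,
        recon_filter=fmap[key],
        body_part=body,
        low_dose=low_dose,
    )
    image_id = str(getattr(ds, "SOPInstanceUID", "")) if not ds.get("SeriesDescription") else str(ds.SeriesDescription)
    return CTImage(pixels=hu, meta=meta, image_id=image_id)


def write_phantom_dicom(image: CTImage, path) -> None:
    """Write a :class:`CTImage` as a Part-10 CT DICOM file.

    Pixels are stored as unsigned 12-in-16-bit values with rescale
    intercept -1024 so that ``read_ct_image`` round-trips the raster and
    all four covariates bit-exactly.
    """
    path = Path(path)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.SeriesDescription = image.image_id or "ctvlt phantom"
    now = datetime.datetime(2020, 1, 1)  # fixed date keeps files reproducible
    ds.ContentDate = now.strftime("%Y%m%d")
    ds.ContentTime = now.strftime("%H%M%S")

    ds.Rows, ds.Columns = image.pixels.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 12
    ds.HighBit = 11
    ds.PixelRepresentation = 0
    ds.RescaleSlope = "1"
    ds.RescaleIntercept = "-1024"
    ds.PixelData = (image.pixels.astype(np.int32) + 1024).astype("<u2").tobytes()

    m = image.meta
    ds.ExposureInmAs = float(m.effective_mas)
    # DS is a 16-byte string VR: 8 significant digits round-trip exactly
    # for the millimetre-scale values stored here.
    ds.SliceThickness = f"{m.section_thickness_mm:.8g}"
    ds.DataCollectionDiameter = f"{m.fov_mm:.8g}"
    ds.ImageFilter = m.recon_filter.upper().replace("-", "_")
    ds.BodyPartExamined = m.body_part.upper()
    if m.low_dose:
        ds.ImageComments = _LOW_DOSE_COMMENT

    ds.save_as(str(path), enforce_file_format=True)
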