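"""Domain types, raster/sidecar I/O and scan quality control.

En-face OCTA images travel as single-channel 8/16-bit TIFF or PNG rasters
with a JSON sidecar carrying geometry (pixel spacing, fovea location) and
acquisition metadata (patient/eye/visit identifiers, signal strength).
Binary exclusion masks use the same raster formats with values in {0, max}.

Coordinate convention: (row, col), 0-based, pixel centers at integer
coordinates.  Lateral spacing is isotropic (one ``pixel_spacing_um`` for
both axes); anisotropic sidecars are rejected at read time.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

logger = logging.getLogger("ccfdgrid")

__all__ = [
    "ScanGeometry",
    "ScanMetadata",
    "EnFaceImage",
    "BinaryMask",
    "VolumeScan",
    "Channel",
    "MaskKind",
    "GroupLabel",
    "QCVerdict",
    "SidecarError",
    "read_enface",
    "write_enface",
    "read_mask",
    "write_mask",
    "qc_check",
]


class SidecarError(ValueError):
    """A required sidecar field is missing or malformed."""

    def __init__(self, fieldname: str, message: str | None = None):
        self.fieldname = fieldname
        super().__init__(message or f"sidecar field missing or invalid: {fieldname}")


class Channel(str, Enum):
    CC_FLOW = "cc_flow"
    CC_STRUCTURE = "cc_structure"
    RETINAL_VASCULATURE = "retinal_vasculature"
    SUB_RPE = "sub_rpe"


class MaskKind(str, Enum):
    HRF = "hrf"
    CAD = "cad"
    HYPERTD = "hypertd"
    PERIPAPILLARY = "peripapillary"
    VITREOUS_SHADOW = "vitreous_shadow"
    VESSEL_PROJECTION = "vessel_projection"
    COMBINED = "combined"
    INTEGRATED = "integrated"
    VALIDITY = "validity"


class GroupLabel(str, Enum):
    NORMAL = "normal"
    IAMD = "iAMD"
    HYPERTD = "hyperTD"
    UNSPECIFIED = "unspecified"


@dataclass(frozen=True)
class ScanGeometry:
    """Raster geometry of an en-face scan.

    ``nominal_fov_mm`` must agree with ``width_px * pixel_spacing_um / 1000``
    to within 1% (a 500-px scan at 12 µm spacing covers a nominal 6 mm).
    """

    width_px: int
    height_px: int
    pixel_spacing_um: float
    fovea_px: tuple[float, float]  # (row, col)
    nominal_fov_mm: float

    def __post_init__(self):
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_spacing_um <= 0:
            raise ValueError("pixel_spacing_um must be positive")
        r, c = self.fovea_px
        if not (0 <= r < self.height_px and 0 <= c < self.width_px):
            raise ValueError(f"fovea_px {self.fovea_px} outside image bounds")
        expected = self.width_px * self.pixel_spacing_um / 1000.0
        if abs(self.nominal_fov_mm - expected) > 0.01 * expected:
            raise ValueError(
                f"nominal_fov_mm {self.nominal_fov_mm} inconsistent with "
                f"{self.width_px} px x {self.pixel_spacing_um} um (= {expected} mm)"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height_px, self.width_px)

    @classmethod
    def create(
        cls,
        width_px: int,
        height_px: int,
        pixel_spacing_um: float,
        fovea_px: tuple[float, float] | None = None,
    ) -> "ScanGeometry":
        """Geometry with nominal FOV derived from size and spacing."""
        if fovea_px is None:
            fovea_px = (height_px / 2.0, width_px / 2.0)
        return cls(
            width_px=width_px,
            height_px=height_px,
            pixel_spacing_um=pixel_spacing_um,
            fovea_px=fovea_px,
            nominal_fov_mm=width_px * pixel_spacing_um / 1000.0,
        )


@dataclass(frozen=True)
class ScanMetadata:
    patient_id: str
    eye_id: str
    visit_id: str
    repeat_index: int = 1
    signal_strength: int = 10
    group_label: GroupLabel = GroupLabel.UNSPECIFIED
    acquisition_date: datetime.date | None = None

    def __post_init__(self):
        if self.repeat_index < 1:
            raise ValueError("repeat_index must be >= 1")
        if not (0 <= self.signal_strength <= 10):
            raise ValueError("signal_strength must be in 0..10")

    @property
    def key(self) -> tuple[str, str, str, int]:
        return (self.patient_id, self.eye_id, self.visit_id, self.repeat_index)


@dataclass
class EnFaceImage:
    """A 2D intensity raster with its geometry and channel tag."""

    pixels: np.ndarray
    geometry: ScanGeometry
    channel: Channel = Channel.CC_FLOW
    metadata: ScanMetadata | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("en-face raster must be 2D single-channel")
        if self.pixels.shape != self.geometry.shape:
            raise ValueError(
                f"raster shape {self.pixels.shape} != geometry {self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel values must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("pixel values must be non-negative")

    def with_pixels(self, pixels: np.ndarray) -> "EnFaceImage":
        return EnFaceImage(pixels, self.geometry, self.channel, self.metadata)


@dataclass
class BinaryMask:
    """A boolean raster; ``True`` marks excluded pixels (or usable pixels
    when ``kind`` is :attr:`MaskKind.VALIDITY`)."""

    pixels: np.ndarray
    geometry: ScanGeometry
    kind: MaskKind = MaskKind.COMBINED

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.shape != self.geometry.shape:
            raise ValueError(
                f"mask shape {self.pixels.shape} != geometry {self.geometry.shape}"
            )

    @property
    def count_true(self) -> int:
        return int(self.pixels.sum())

    def with_kind(self, kind: MaskKind) -> "BinaryMask":
        return BinaryMask(self.pixels.copy(), self.geometry, kind)

    @classmethod
    def empty(cls, geometry: ScanGeometry, kind: MaskKind = MaskKind.COMBINED):
        return cls(np.zeros(geometry.shape, dtype=bool), geometry, kind)

    @classmethod
    def full(cls, geometry: ScanGeometry, kind: MaskKind = MaskKind.VALIDITY):
        return cls(np.ones(geometry.shape, dtype=bool), geometry, kind)


@dataclass
class VolumeScan:
    """Paired OCTA flow / OCT structure volumes with a Bruch's-membrane
    depth surface, from which en-face slabs are extracted."""

    flow_voxels: np.ndarray  # rows x cols x depth
    structure_voxels: np.ndarray
    axial_spacing_um: float
    bm_surface_px: np.ndarray  # depth index of BM per (row, col)
    geometry: ScanGeometry

    def __post_init__(self):
        self.flow_voxels = np.asarray(self.flow_voxels, dtype=np.float64)
        self.structure_voxels = np.asarray(self.structure_voxels, dtype=np.float64)
        self.bm_surface_px = np.asarray(self.bm_surface_px)
        if self.flow_voxels.shape != self.structure_voxels.shape:
            raise ValueError("flow and structure volumes must share a shape")
        if self.flow_voxels.ndim != 3:
            raise ValueError("volumes must be 3D (rows x cols x depth)")
        if self.flow_voxels.shape[:2] != self.geometry.shape:
            raise ValueError("volume lateral shape must match geometry")
        if self.bm_surface_px.shape != self.geometry.shape:
            raise ValueError("BM surface shape must match geometry")
        if self.axial_spacing_um <= 0:
            raise ValueError("axial_spacing_um must be positive")
        depth = self.flow_voxels.shape[2]
        if np.any(self.bm_surface_px < 0) or np.any(self.bm_surface_px >= depth):
            raise ValueError("BM surface indices outside volume depth")


@dataclass(frozen=True)
class QCVerdict:
    passed: bool
    reasons: tuple[str, ...] = ()

    def __bool__(self) -> bool:
        return self.passed


# --------------------------------------------------------------------------
# sidecar handling

_KNOWN_SIDECAR_KEYS = {
    "pixel_spacing_um",
    "fovea_px",
    "patient_id",
    "eye_id",
    "visit_id",
    "repeat_index",
    "signal_strength",
    "group_label",
    "acquisition_date",
    "channel",
    "kind",
    "nominal_fov_mm",
}


def _load_sidecar(sidecar: str | Path) -> dict:
    sidecar = Path(sidecar)
    if not sidecar.exists():
        raise SidecarError("sidecar", f"sidecar file not found: {sidecar}")
    with open(sidecar) as fh:
        data = json.load(fh)
    unknown = set(data) - _KNOWN_SIDECAR_KEYS
    if unknown:
        logger.warning("ignoring unknown sidecar keys: %s", sorted(unknown))
    return data


def _geometry_from_sidecar(data: dict, shape: tuple[int, int]) -> ScanGeometry:
    if "pixel_spacing_um" not in data:
        raise SidecarError("pixel_spacing_um")
    spacing = data["pixel_spacing_um"]
    if isinstance(spacing, (list, tuple)):
        if len(set(spacing)) != 1:
            raise SidecarError(
                "pixel_spacing_um",
                "pixel_spacing_um: anisotropic pixel spacing is not supported",
            )
        spacing = spacing[0]
    if "fovea_px" not in data:
        raise SidecarError("fovea_px")
    fovea = tuple(float(v) for v in data["fovea_px"])
    h, w = shape
    return ScanGeometry.create(w, h, float(spacing), fovea)


def _metadata_from_sidecar(data: dict) -> ScanMetadata | None:
    if "patient_id" not in data:
        return None
    date = data.get("acquisition_date")
    return ScanMetadata(
        patient_id=str(data["patient_id"]),
        eye_id=str(data.get("eye_id", "")),
        visit_id=str(data.get("visit_id", "")),
        repeat_index=int(data.get("repeat_index", 1)),
        signal_strength=int(data.get("signal_strength", 10)),
        group_label=GroupLabel(data.get("group_label", "unspecified")),
        acquisition_date=datetime.date.fromisoformat(date) if date else None,
    )


def _read_raster(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel raster, got shape {arr.shape}")
    return arr


def _write_raster(path: str | Path, arr: np.ndarray) -> None:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


# --------------------------------------------------------------------------
# public I/O


def read_enface(path: str | Path, sidecar: str | Path) -> EnFaceImage:
    """Read a single-channel 8/16-bit raster and its JSON sidecar.

    Pixel values are preserved losslessly as floats; round-trips with
    :func:`write_enface`.
    """
    arr = _read_raster(path)
    data = _load_sidecar(sidecar)
    geometry = _geometry_from_sidecar(data, arr.shape)
    channel = Channel(data.get("channel", "cc_flow"))
    meta = _metadata_from_sidecar(data)
    return EnFaceImage(arr.astype(np.float64), geometry, channel, meta)


def write_enface(img: EnFaceImage, path: str | Path, sidecar: str | Path) -> None:
    """Write an en-face image as a 16-bit (or 8-bit if it fits) raster plus
    JSON sidecar.  Values must be integral and within the chosen bit depth."""
    px = img.pixels
    if not np.allclose(px, np.round(px)):
        raise ValueError("write_enface stores integer rasters; scale first")
    if px.max(initial=0) > 65535:
        raise ValueError("pixel values exceed 16-bit range")
    dtype = np.uint8 if px.max(initial=0) <= 255 else np.uint16
    _write_raster(path, px.astype(dtype))
    data = {
        "pixel_spacing_um": img.geometry.pixel_spacing_um,
        "fovea_px": list(img.geometry.fovea_px),
        "nominal_fov_mm": img.geometry.nominal_fov_mm,
        "channel": img.channel.value,
    }
    if img.metadata is not None:
        m = img.metadata
        data.update(
            patient_id=m.patient_id,
            eye_id=m.eye_id,
            visit_id=m.visit_id,
            repeat_index=m.repeat_index,
            signal_strength=m.signal_strength,
            group_label=m.group_label.value,
        )
        if m.acquisition_date is not None:
            data["acquisition_date"] = m.acquisition_date.isoformat()
    with open(sidecar, "w") as fh:
        json.dump(data, fh, indent=1)


def read_mask(path: str | Path, sidecar: str | Path, kind: MaskKind | str) -> BinaryMask:
    """Read a binary mask raster (values must be exactly {0, max})."""
    arr = _read_raster(path)
    vals = np.unique(arr)
    nonzero = vals[vals != 0]
    if nonzero.size > 1:
        raise ValueError(
            f"{path}: mask rasters must be binary; found values {vals.tolist()}"
        )
    data = _load_sidecar(sidecar)
    geometry = _geometry_from_sidecar(data, arr.shape)
    return BinaryMask(arr != 0, geometry, MaskKind(kind))


def write_mask(mask: BinaryMask, path: str | Path, sidecar: str | Path) -> None:
    _write_raster(path, mask.pixels.astype(np.uint8) * 255)
    data = {
        "pixel_spacing_um": mask.geometry.pixel_spacing_um,
        "fovea_px": list(mask.geometry.fovea_px),
        "kind": mask.kind.value,
    }
    with open(sidecar, "w") as fh:
        json.dump(data, fh, indent=1)


# --------------------------------------------------------------------------
# quality control

QC_MIN_SIGNAL_STRENGTH = 7
KNOWN_QC_FLAGS = frozenset({"motion", "illumination"})


def qc_check(meta: ScanMetadata, flags: frozenset[str] | set[str] = frozenset()) -> QCVerdict:
    """Scan-level quality control.

    A scan fails if signal strength is below 7 or if the operator flagged
    significant motion artifacts or insufficient illumination.  Pure
    function; the verdict enumerates every failure reason.
    """
    reasons: list[str] = []
    if meta.signal_strength < QC_MIN_SIGNAL_STRENGTH:
        reasons.append(f"signal_strength<{QC_MIN_SIGNAL_STRENGTH}")
    for flag in sorted(flags):
        if flag in KNOWN_QC_FLAGS:
            reasons.append(flag)
        else:
            logger.warning("unknown QC flag ignored: %s", flag)
    return QCVerdict(passed=not reasons, reasons=tuple(reasons))
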