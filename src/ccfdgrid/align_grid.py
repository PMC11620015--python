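"""Scan registration, integrated masks, grid/circle ROIs and CCFD%.

Repeat scans of the same eye are registered on their retinal-vasculature
en-face images (the first scan is the baseline frame); the per-scan
combined masks plus the off-overlap regions are merged into a single
integrated mask so only regions with meaningful CC measurements across all
scans are compared.  ROIs are 3-mm and 5-mm fovea-centered circles and a
grid of complete 74x74-px boxes tiled outward from a target box; CCFD% is
the deficit-pixel fraction of the valid (unmasked) pixels in each ROI.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from skimage.transform import rotate as _sk_rotate

from .ccfd_quant import FlowDeficitMap
from .scan_io import BinaryMask, EnFaceImage, MaskKind, ScanGeometry, ScanMetadata

logger = logging.getLogger("ccfdgrid")

__all__ = [
    "RigidTransform",
    "RegistrationConfig",
    "GridBox",
    "Grid",
    "CircleROI",
    "ROIMeasurement",
    "QuantifiedScan",
    "VisitMeasurement",
    "register_enface",
    "apply_transform",
    "merge_masks",
    "build_integrated_mask",
    "build_grid",
    "build_circle_roi",
    "compute_ccfd_percent",
    "measure_visit_set",
]

DEFAULT_BOX_SIZE_PX = 74


@dataclass(frozen=True)
class RigidTransform:
    """Rigid displacement (row shift, col shift, rotation about the image
    center).  ``apply_transform(img, t)`` moves image content by
    (dy, dx) after rotating by theta; registration returns the displacement
    of the moving image relative to the fixed one, so aligning uses
    ``t.invert()``."""

    dy_px: float
    dx_px: float
    theta_deg: float = 0.0
    score: float = float("nan")

    def invert(self) -> "RigidTransform":
        th = math.radians(self.theta_deg)
        # inverse of shift(rotate(x, th), d) is shift(rotate(y, -th), -R(-th) d)
        cos, sin = math.cos(-th), math.sin(-th)
        dy, dx = self.dy_px, self.dx_px
        return RigidTransform(
            dy_px=-(cos * dy - sin * dx),
            dx_px=-(sin * dy + cos * dx),
            theta_deg=-self.theta_deg,
            score=self.score,
        )

    @property
    def is_identity(self) -> bool:
        return self.dy_px == 0 and self.dx_px == 0 and self.theta_deg == 0


@dataclass(frozen=True)
class RegistrationConfig:
    max_shift_px: int = 100
    rotation_search: bool = False
    rotation_max_deg: float = 5.0
    rotation_step_deg: float = 0.25
    min_score: float = 0.2
    min_overlap_fraction: float = 0.25


def _masked_ncc(moving: np.ndarray, fixed: np.ndarray, max_shift: int, min_overlap: float):
    """Normalized cross-correlation over all integer lags, each lag scored
    on its actual overlap region (masked NCC via FFT)."""
    m = moving.astype(np.float64)
    f = fixed.astype(np.float64)
    ones_m = np.ones_like(m)
    ones_f = np.ones_like(f)
    flip = (slice(None, None, -1), slice(None, None, -1))

    def xcorr(a, b):
        return fftconvolve(a, b[flip], mode="full")

    n = xcorr(ones_m, ones_f)
    s_mf = xcorr(m, f)
    s_m = xcorr(m, ones_f)
    s_f = xcorr(ones_m, f)
    s_m2 = xcorr(m**2, ones_f)
    s_f2 = xcorr(ones_m, f**2)

    n = np.maximum(n, 1e-9)
    cov = s_mf - s_m * s_f / n
    var_m = np.maximum(s_m2 - s_m**2 / n, 0.0)
    var_f = np.maximum(s_f2 - s_f**2 / n, 0.0)
    denom = np.sqrt(var_m * var_f)
    with np.errstate(invalid="ignore", divide="ignore"):
        ncc = np.where(denom > 1e-9, cov / np.maximum(denom, 1e-300), -np.inf)

    h, w = m.shape
    cy, cx = h - 1, w - 1  # zero-lag index in the 'full' correlation
    lo_y, hi_y = max(0, cy - max_shift), min(ncc.shape[0], cy + max_shift + 1)
    lo_x, hi_x = max(0, cx - max_shift), min(ncc.shape[1], cx + max_shift + 1)
    window = ncc[lo_y:hi_y, lo_x:hi_x].copy()
    n_window = n[lo_y:hi_y, lo_x:hi_x]
    window[n_window < min_overlap * m.size] = -np.inf
    iy, ix = np.unravel_index(np.argmax(window), window.shape)
    dy = iy + lo_y - cy
    dx = ix + lo_x - cx
    return int(dy), int(dx), float(window[iy, ix])


def register_enface(
    moving: EnFaceImage, fixed: EnFaceImage, cfg: RegistrationConfig = RegistrationConfig()
) -> RigidTransform:
    """Estimate the rigid displacement of ``moving`` relative to ``fixed``.

    Translation by correlation-peak search over integer pixel lags; optional
    exhaustive rotation search over ±``rotation_max_deg`` in
    ``rotation_step_deg`` steps (off by default).  The score is the
    normalized correlation at the optimum; below ``min_score`` registration
    is considered failed.
    """
    if moving.geometry.shape != fixed.geometry.shape:
        raise ValueError("registration requires equal scan shapes")
    thetas = [0.0]
    if cfg.rotation_search:
        n_steps = int(round(cfg.rotation_max_deg / cfg.rotation_step_deg))
        thetas = [i * cfg.rotation_step_deg for i in range(-n_steps, n_steps + 1)]
    best: RigidTransform | None = None
    for theta in thetas:
        if theta == 0.0:
            candidate = fixed.pixels
        else:
            candidate = _sk_rotate(fixed.pixels, theta, preserve_range=True, order=1)
        dy, dx, score = _masked_ncc(
            moving.pixels, candidate, cfg.max_shift_px, cfg.min_overlap_fraction
        )
        if best is None or score > best.score:
            best = RigidTransform(dy_px=dy, dx_px=dx, theta_deg=theta, score=score)
    assert best is not None
    if not np.isfinite(best.score) or best.score < cfg.min_score:
        raise ValueError(
            f"registration failed: best correlation {best.score:.3f} < {cfg.min_score}"
        )
    return best


def apply_transform(
    img: EnFaceImage | BinaryMask | FlowDeficitMap, t: RigidTransform
):
    """Apply a rigid transform; returns (same type, validity mask).

    Intensity rasters are resampled bilinearly, binary rasters with nearest
    neighbor; pure integer translations are applied exactly by slicing.
    The validity mask marks pixels mapped from inside the source raster.
    """
    is_binary = isinstance(img, (BinaryMask, FlowDeficitMap))
    src = img.pixels
    h, w = src.shape
    valid = np.zeros((h, w), dtype=bool)

    integer_shift = (
        t.theta_deg == 0
        and float(t.dy_px).is_integer()
        and float(t.dx_px).is_integer()
    )
    if integer_shift:
        dy, dx = int(t.dy_px), int(t.dx_px)
        out = np.zeros_like(src)
        src_r = slice(max(0, -dy), min(h, h - dy))
        src_c = slice(max(0, -dx), min(w, w - dx))
        dst_r = slice(max(0, dy), min(h, h + dy))
        dst_c = slice(max(0, dx), min(w, w + dx))
        if src_r.stop > src_r.start and src_c.stop > src_c.start:
            out[dst_r, dst_c] = src[src_r, src_c]
            valid[dst_r, dst_c] = True
    else:
        work = src.astype(np.float64)
        if t.theta_deg != 0:
            work = _sk_rotate(work, t.theta_deg, preserve_range=True, order=0 if is_binary else 1)
            vmask = _sk_rotate(np.ones((h, w)), t.theta_deg, preserve_range=True, order=0)
        else:
            vmask = np.ones((h, w))
        from scipy.ndimage import shift as _nd_shift

        order = 0 if is_binary else 1
        work = _nd_shift(work, (t.dy_px, t.dx_px), order=order, cval=0.0)
        vmask = _nd_shift(vmask, (t.dy_px, t.dx_px), order=0, cval=0.0)
        valid = vmask > 0.5
        out = (work > 0.5) if is_binary else np.clip(work, 0.0, None)

    validity = BinaryMask(valid, img.geometry, MaskKind.VALIDITY)
    if isinstance(img, FlowDeficitMap):
        moved = FlowDeficitMap(
            out.astype(bool), img.geometry, img.source_threshold, img.min_gld_um
        )
    elif isinstance(img, BinaryMask):
        moved = BinaryMask(out.astype(bool), img.geometry, img.kind)
    else:
        moved = img.with_pixels(out)
    return moved, validity


def merge_masks(masks: list[BinaryMask]) -> BinaryMask:
    """Pixelwise union of exclusion masks (the per-scan 'combined mask')."""
    if not masks:
        raise ValueError("merge_masks requires at least one mask")
    geometry = masks[0].geometry
    out = np.zeros(geometry.shape, dtype=bool)
    for m in masks:
        if m.geometry.shape != geometry.shape:
            raise ValueError("mask geometry mismatch in merge_masks")
        out |= m.pixels
    return BinaryMask(out, geometry, MaskKind.COMBINED)


def build_integrated_mask(
    registered_combined: list[BinaryMask], validity: list[BinaryMask]
) -> BinaryMask:
    """Cross-scan integrated mask: union of the registered combined masks
    and of every off-overlap (invalid) region, applied identically to every
    scan's FD map."""
    if not registered_combined:
        raise ValueError("build_integrated_mask requires at least one mask")
    geometry = registered_combined[0].geometry
    out = np.zeros(geometry.shape, dtype=bool)
    for m in registered_combined:
        out |= m.pixels
    for v in validity:
        out |= ~v.pixels
    return BinaryMask(out, geometry, MaskKind.INTEGRATED)


# --------------------------------------------------------------------------
# ROIs


@dataclass(frozen=True)
class GridBox:
    row_start: int
    col_start: int
    size_px: int = DEFAULT_BOX_SIZE_PX
    index: tuple[int, int] = (0, 0)  # (i, j) offsets from the target box
    is_target: bool = False

    @property
    def box_id(self) -> str:
        return f"box_{self.index[0]:+d}_{self.index[1]:+d}"

    @property
    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row_start, self.row_start + self.size_px),
            slice(self.col_start, self.col_start + self.size_px),
        )


@dataclass(frozen=True)
class Grid:
    boxes: tuple[GridBox, ...]
    center_px: tuple[float, float]
    box_size_px: int

    @property
    def target_box(self) -> GridBox:
        return next(b for b in self.boxes if b.is_target)

    def area_mm2(self, pixel_spacing_um: float) -> float:
        side_mm = self.box_size_px * pixel_spacing_um / 1000.0
        return len(self.boxes) * side_mm**2

    def descriptor(self) -> dict:
        return {
            "center_px": list(self.center_px),
            "box_size_px": self.box_size_px,
            "boxes": [
                {
                    "index": list(b.index),
                    "row_start": b.row_start,
                    "col_start": b.col_start,
                    "is_target": b.is_target,
                }
                for b in self.boxes
            ],
        }


@dataclass(frozen=True)
class CircleROI:
    center_px: tuple[float, float]
    diameter_mm: float

    def __post_init__(self):
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be positive")

    @property
    def roi_id(self) -> str:
        return f"circle_{self.diameter_mm:g}mm"


@dataclass(frozen=True)
class ROIMeasurement:
    roi_id: str
    ccfd_percent: float | None
    valid_px: int
    total_px: int

    @property
    def valid_fraction(self) -> float:
        return self.valid_px / self.total_px if self.total_px else 0.0


def build_grid(
    center_px: tuple[float, float],
    validity: BinaryMask,
    box_size_px: int = DEFAULT_BOX_SIZE_PX,
) -> Grid:
    """Tile complete boxes outward from a target box centered on
    ``center_px``.

    The target box is anchored at ``round(center) - size // 2`` (the center
    pixel sits in the box's upper-left quadrant for an even box size) and
    boxes propagate on the lattice of multiples of the box size.  A box is
    retained iff every pixel lies inside scan bounds and inside the
    validity region — complete boxes only; partial masking inside a
    retained box is handled by the valid-pixel denominator downstream.
    """
    if box_size_px < 1:
        raise ValueError("box_size_px must be >= 1")
    h, w = validity.geometry.shape
    s = box_size_px
    r0 = int(round(center_px[0])) - s // 2
    c0 = int(round(center_px[1])) - s // 2
    vpx = validity.pixels

    def complete(rs: int, cs: int) -> bool:
        if rs < 0 or cs < 0 or rs + s > h or cs + s > w:
            return False
        return bool(vpx[rs : rs + s, cs : cs + s].all())

    if not complete(r0, c0):
        raise ValueError("target box does not fit inside the valid region")
    boxes = []
    i_min, i_max = -(r0 // s) - 1, (h - r0) // s + 1
    j_min, j_max = -(c0 // s) - 1, (w - c0) // s + 1
    for i in range(i_min, i_max + 1):
        for j in range(j_min, j_max + 1):
            rs, cs = r0 + i * s, c0 + j * s
            if complete(rs, cs):
                boxes.append(
                    GridBox(rs, cs, s, index=(i, j), is_target=(i == 0 and j == 0))
                )
    return Grid(tuple(boxes), tuple(float(v) for v in center_px), s)


def build_circle_roi(
    center_px: tuple[float, float], diameter_mm: float, geometry: ScanGeometry
) -> BinaryMask:
    """Fovea-centered circular ROI: a pixel is included iff its center lies
    within diameter/2 of the ROI center (µm via the pixel spacing).
    Circles extending past the scan bounds are clipped with a warning."""
    radius_px = (diameter_mm * 1000.0 / 2.0) / geometry.pixel_spacing_um
    h, w = geometry.shape
    rr, cc = np.ogrid[:h, :w]
    dist = np.sqrt((rr - center_px[0]) ** 2 + (cc - center_px[1]) ** 2)
    inside = dist <= radius_px
    cy, cx = center_px
    if cy - radius_px < -0.5 or cx - radius_px < -0.5 or cy + radius_px > h - 0.5 or cx + radius_px > w - 0.5:
        full_area = math.pi * radius_px**2
        clip_fraction = max(0.0, 1.0 - inside.sum() / full_area)
        logger.warning(
            "circle ROI (%.3g mm) extends past scan bounds; clipped ~%.1f%%",
            diameter_mm,
            100 * clip_fraction,
        )
    return BinaryMask(inside, geometry, MaskKind.VALIDITY)


def _roi_pixels(roi, geometry: ScanGeometry) -> tuple[np.ndarray, str]:
    if isinstance(roi, GridBox):
        sel = np.zeros(geometry.shape, dtype=bool)
        sel[roi.slices] = True
        return sel, roi.box_id
    if isinstance(roi, Grid):
        sel = np.zeros(geometry.shape, dtype=bool)
        for b in roi.boxes:
            sel[b.slices] = True
        return sel, "grid_total"
    if isinstance(roi, CircleROI):
        mask = build_circle_roi(roi.center_px, roi.diameter_mm, geometry)
        return mask.pixels, roi.roi_id
    if isinstance(roi, BinaryMask):
        return roi.pixels, "roi"
    raise TypeError(f"unsupported ROI type: {type(roi).__name__}")


def compute_ccfd_percent(
    fd: FlowDeficitMap, integrated: BinaryMask | None, roi
) -> ROIMeasurement:
    """CCFD% of an ROI: 100 x deficit pixels / valid pixels, where valid =
    ROI minus the integrated mask.  Grid totals pool pixels across boxes
    rather than averaging box percentages.  A fully masked ROI yields a
    null percentage (never a silent 0%)."""
    sel, roi_id = _roi_pixels(roi, fd.geometry)
    valid = sel if integrated is None else (sel & ~integrated.pixels)
    total_px = int(sel.sum())
    valid_px = int(valid.sum())
    if valid_px == 0:
        return ROIMeasurement(roi_id, None, 0, total_px)
    fd_px = int((fd.pixels & valid).sum())
    return ROIMeasurement(roi_id, 100.0 * fd_px / valid_px, valid_px, total_px)


# --------------------------------------------------------------------------
# visit-level measurement


@dataclass
class QuantifiedScan:
    """A quantified repeat scan ready for registration: its retinal
    vasculature en-face, filtered FD map, combined mask, and identifiers."""

    retina: EnFaceImage
    fd: FlowDeficitMap
    combined: BinaryMask
    metadata: ScanMetadata


@dataclass
class VisitMeasurement:
    table: "pd.DataFrame"  # noqa: F821  (constructed in measure_visit_set)
    grid: Grid
    integrated: BinaryMask
    transforms: list[RigidTransform]


def measure_visit_set(
    scans: list[QuantifiedScan],
    center_px: tuple[float, float] | None = None,
    box_size_px: int = DEFAULT_BOX_SIZE_PX,
    circle_diameters_mm: tuple[float, ...] = (3.0, 5.0),
    registration: RegistrationConfig = RegistrationConfig(),
) -> VisitMeasurement:
    """Register a set of repeat scans to the first (baseline) scan, build
    the integrated mask, grid and circles once, and measure CCFD% for every
    (scan, ROI) pair.

    Returns a long-format table with one row per scan and ROI.  ``center_px``
    defaults to the baseline fovea; for lesion-tracking analyses pass the
    lesion center instead so the target box covers it.
    """
    import pandas as pd

    if not scans:
        raise ValueError("measure_visit_set requires at least one scan")
    baseline = scans[0]
    geometry = baseline.retina.geometry
    if center_px is None:
        center_px = geometry.fovea_px

    transforms: list[RigidTransform] = []
    reg_fd: list[FlowDeficitMap] = []
    reg_combined: list[BinaryMask] = []
    validities: list[BinaryMask] = []
    for scan in scans:
        if scan is baseline:
            t = RigidTransform(0, 0, 0.0, score=1.0)
        else:
            try:
                t = register_enface(scan.retina, baseline.retina, registration)
            except ValueError as exc:
                raise ValueError(
                    f"registration failed for scan "
                    f"{scan.metadata.key if scan.metadata else '?'}: {exc}"
                ) from exc
        transforms.append(t)
        align = t.invert()
        fd_r, validity = apply_transform(scan.fd, align)
        cm_r, _ = apply_transform(scan.combined, align)
        reg_fd.append(fd_r)
        reg_combined.append(cm_r)
        validities.append(validity)

    integrated = build_integrated_mask(reg_combined, validities)
    overlap_validity = BinaryMask(
        np.logical_and.reduce([v.pixels for v in validities]), geometry, MaskKind.VALIDITY
    )
    grid = build_grid(center_px, overlap_validity, box_size_px)
    circles = [CircleROI(center_px, d) for d in circle_diameters_mm]

    rows = []
    dropped_null = 0
    for scan, fd_r in zip(scans, reg_fd):
        meta = scan.metadata
        rois: list = list(circles) + list(grid.boxes) + [grid]
        for roi in rois:
            m = compute_ccfd_percent(fd_r, integrated, roi)
            if m.ccfd_percent is None:
                dropped_null += 1
            if isinstance(roi, CircleROI):
                roi_type = "circle"
            elif isinstance(roi, Grid):
                roi_type = "grid_total"
            else:
                roi_type = "box"
            rows.append(
                {
                    "patient_id": meta.patient_id if meta else "",
                    "eye_id": meta.eye_id if meta else "",
                    "visit_id": meta.visit_id if meta else "",
                    "repeat_index": meta.repeat_index if meta else 1,
                    "group_label": meta.group_label.value if meta else "unspecified",
                    "roi_type": roi_type,
                    "roi_id": m.roi_id,
                    "ccfd_percent": np.nan if m.ccfd_percent is None else m.ccfd_percent,
                    "valid_px": m.valid_px,
                    "total_px": m.total_px,
                    "valid_fraction": m.valid_fraction,
                }
            )
    if dropped_null:
        logger.info("%d fully masked ROI measurements recorded as null", dropped_null)
    return VisitMeasurement(pd.DataFrame(rows), grid, integrated, transforms)
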