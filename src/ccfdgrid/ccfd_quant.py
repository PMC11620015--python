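"""Flow-deficit quantification on choriocapillaris en-face images.

The processing chain mirrors the per-scan half of the grid workflow:

1. slab extraction from a BM-referenced volume (CC slab: a 16-µm slab
   starting 4 µm below Bruch's membrane);
2. signal-attenuation compensation of the flow image using the structure
   image from the same slab (drusen and RPE abnormalities attenuate both);
3. exclusion masking (lesion masks merged with a retinal-vessel-projection
   mask derived from the retinal-vasculature en-face image);
4. global Fuzzy C-means thresholding of the unmasked compensated flow;
5. removal of deficits whose greatest linear dimension (GLD) is below
   24 µm, the scale of physiological intercapillary flow voids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .scan_io import BinaryMask, Channel, EnFaceImage, MaskKind, ScanGeometry, VolumeScan

logger = logging.getLogger("ccfdgrid")

__all__ = [
    "SlabDefinition",
    "CC_SLAB",
    "SUB_RPE_SLAB",
    "ThresholdResult",
    "FlowDeficitMap",
    "CompensationConfig",
    "QuantConfig",
    "extract_slab",
    "compensate_flow",
    "derive_vessel_projection_mask",
    "fcm_threshold",
    "binarize_flow",
    "filter_small_deficits",
    "quantify_scan",
]


@dataclass(frozen=True)
class SlabDefinition:
    """Depth interval below Bruch's membrane, positive downward (µm)."""

    offset_start_um: float
    thickness_um: float
    projection: str = "mean"  # or "max"

    def __post_init__(self):
        if self.thickness_um <= 0:
            raise ValueError("thickness_um must be positive")
        if self.offset_start_um < 0:
            raise ValueError("offset_start_um must be >= 0")
        if self.projection not in ("mean", "max"):
            raise ValueError("projection must be 'mean' or 'max'")


#: The choriocapillaris slab: 16 µm thick, starting 4 µm below BM.
CC_SLAB = SlabDefinition(offset_start_um=4.0, thickness_um=16.0)
#: The sub-RPE slab used for lesion review: 64–400 µm below BM.
SUB_RPE_SLAB = SlabDefinition(offset_start_um=64.0, thickness_um=336.0)


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float
    cluster_centers: tuple[float, float]  # (low, high)
    iterations: int
    converged: bool

    def __post_init__(self):
        low, high = self.cluster_centers
        if not (low < self.threshold < high):
            raise ValueError("threshold must lie strictly between cluster centers")


@dataclass
class FlowDeficitMap:
    """Binary flow-deficit raster (True = deficit) plus provenance."""

    pixels: np.ndarray
    geometry: ScanGeometry
    source_threshold: ThresholdResult | None = None
    min_gld_um: float = 0.0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.shape != self.geometry.shape:
            raise ValueError("FD map shape must match geometry")

    @property
    def count_true(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class CompensationConfig:
    mode: str = "divide"  # "divide" | "complement" | "off"
    sigma_px: float = 2.0
    floor_quantile: float = 0.05

    def __post_init__(self):
        if self.mode not in ("divide", "complement", "off"):
            raise ValueError("compensation mode must be divide/complement/off")
        if not (0.0 <= self.floor_quantile < 1.0):
            raise ValueError("floor_quantile must be in [0, 1)")


@dataclass(frozen=True)
class QuantConfig:
    """All tunables of the per-scan quantification chain."""

    compensation: CompensationConfig = field(default_factory=CompensationConfig)
    fcm_max_iter: int = 300
    fcm_tol: float = 1e-6
    min_gld_um: float = 24.0
    vessel_threshold: float | None = None  # None = automatic (Otsu)
    vessel_dilation_px: int = 1
    cc_slab: SlabDefinition = CC_SLAB


# --------------------------------------------------------------------------
# slab extraction


def extract_slab(vol: VolumeScan, slab: SlabDefinition, channel: Channel) -> EnFaceImage:
    """Project a BM-referenced depth interval of a volume to an en-face image.

    A voxel at depth index ``d`` in column (r, c) belongs to the slab iff its
    depth below BM, ``(d - bm[r, c]) * axial_spacing_um``, lies in
    ``[offset_start, offset_start + thickness)``.
    """
    voxels = vol.flow_voxels if channel == Channel.CC_FLOW else vol.structure_voxels
    nrows, ncols, ndepth = voxels.shape
    spacing = vol.axial_spacing_um
    bm = np.asarray(vol.bm_surface_px, dtype=np.int64)

    # first index with (d - bm)*spacing >= offset  ->  d >= bm + ceil(offset/spacing)
    lo_off = int(np.ceil(slab.offset_start_um / spacing - 1e-9))
    # last index with (d - bm)*spacing < offset + thickness
    hi_off = int(np.ceil((slab.offset_start_um + slab.thickness_um) / spacing - 1e-9))
    if hi_off <= lo_off:
        raise ValueError("slab thinner than one axial sample")
    n_slab = hi_off - lo_off

    too_deep = bm + hi_off - 1 >= ndepth
    if np.any(too_deep):
        r, c = np.argwhere(too_deep)[0]
        raise ValueError(
            f"slab exceeds volume depth at pixel (row={r}, col={c}): "
            f"BM index {bm[r, c]} + slab end {hi_off - 1} >= depth {ndepth}"
        )

    depth_idx = bm[:, :, None] + np.arange(lo_off, hi_off)[None, None, :]
    rows = np.arange(nrows)[:, None, None]
    cols = np.arange(ncols)[None, :, None]
    slab_vox = voxels[rows, cols, depth_idx]
    if slab.projection == "mean":
        proj = slab_vox.mean(axis=2)
    else:
        proj = slab_vox.max(axis=2)
    assert proj.shape == (nrows, ncols) and n_slab == slab_vox.shape[2]
    return EnFaceImage(proj, vol.geometry, channel)


# --------------------------------------------------------------------------
# compensation


def compensate_flow(
    flow: EnFaceImage,
    structure: EnFaceImage,
    cfg: CompensationConfig = CompensationConfig(),
    exclude: BinaryMask | None = None,
) -> EnFaceImage:
    """Compensate the CC flow image for OCT signal attenuation using the CC
    structure image.

    Attenuation from overlying material (drusen, hyperreflective RPE) is,
    to first order, a shared multiplicative factor on flow and structure.
    The default ``divide`` mode therefore divides the flow image by the
    smoothed structure image (floored at a low quantile so noise-level
    structure does not blow up) and rescales so the median over unmasked
    pixels matches the input flow — exact removal of shared multiplicative
    attenuation.  ``complement`` mode multiplies the flow image by the
    inverted (max − value) smoothed structure image instead, with the same
    median-preserving rescale.
    """
    if flow.geometry.shape != structure.geometry.shape:
        raise ValueError("flow and structure geometries differ")
    if cfg.mode == "off":
        return flow.with_pixels(flow.pixels.copy())
    struct_px = structure.pixels
    if not np.any(struct_px > 0):
        raise ValueError("degenerate structure image (all zero)")
    smooth = ndimage.gaussian_filter(struct_px, sigma=cfg.sigma_px)
    unmasked = (
        np.ones(flow.geometry.shape, dtype=bool)
        if exclude is None
        else ~exclude.pixels
    )
    if cfg.mode == "divide":
        floor = np.quantile(smooth[unmasked], cfg.floor_quantile)
        floor = max(floor, np.finfo(float).tiny)
        comp = flow.pixels / np.maximum(smooth, floor)
    else:  # complement
        inverted = smooth[unmasked].max() - smooth
        comp = flow.pixels * inverted
    med_in = np.median(flow.pixels[unmasked])
    med_out = np.median(comp[unmasked])
    if med_out > 0:
        comp = comp * (med_in / med_out)
    return flow.with_pixels(np.clip(comp, 0.0, None))


# --------------------------------------------------------------------------
# retinal vessel projection mask


def derive_vessel_projection_mask(
    retina: EnFaceImage,
    exclude: BinaryMask | None = None,
    threshold: float | None = None,
    dilation_px: int = 1,
) -> BinaryMask:
    """Segment bright retinal vessels on the retinal-vasculature en-face and
    dilate them into an exclusion mask for projection artifacts.

    The threshold defaults to the between-class-variance maximizer (Otsu)
    over unmasked pixels; a fixed threshold can be supplied instead.
    """
    px = retina.pixels
    unmasked = np.ones(px.shape, dtype=bool) if exclude is None else ~exclude.pixels
    values = px[unmasked]
    if threshold is None:
        if np.ptp(values) == 0:
            logger.warning("constant retinal image: vessel mask left empty")
            return BinaryMask.empty(retina.geometry, MaskKind.VESSEL_PROJECTION)
        threshold = float(threshold_otsu(values))
    vessels = px > threshold
    if dilation_px > 0:
        vessels = ndimage.binary_dilation(vessels, structure=disk(dilation_px))
    return BinaryMask(vessels, retina.geometry, MaskKind.VESSEL_PROJECTION)


# --------------------------------------------------------------------------
# fuzzy C-means global threshold

_FCM_HIST_BINS = 256


def _fcm_1d(
    values: np.ndarray,
    weights: np.ndarray,
    init_centers: tuple[float, float],
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, int, bool]:
    """Weighted 2-cluster fuzzy C-means on 1D data, fuzzifier m = 2.

    With m = 2 the membership of value x in cluster i is
    ``u_i(x) = (1/d_i^2) / sum_j (1/d_j^2)`` with d the center distance, and
    each center update is the u^2-weighted mean.
    """
    centers = np.array(init_centers, dtype=np.float64)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d2 = (values[:, None] - centers[None, :]) ** 2
        d2 = np.maximum(d2, 1e-300)
        inv = 1.0 / d2
        u = inv / inv.sum(axis=1, keepdims=True)
        w2 = (u**2) * weights[:, None]
        new_centers = (w2 * values[:, None]).sum(axis=0) / w2.sum(axis=0)
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if shift < tol:
            converged = True
            break
    return np.sort(centers), it, converged


def fcm_threshold(
    img: EnFaceImage,
    exclude: BinaryMask | None = None,
    max_iter: int = 300,
    tol: float = 1e-6,
    bins: int = _FCM_HIST_BINS,
) -> ThresholdResult:
    """Global Fuzzy C-means threshold of the unmasked intensity distribution.

    Two clusters (deficit/background), fuzzifier m = 2, centers initialized
    at the 10th and 90th percentiles of unmasked intensities, iterated on a
    256-bin histogram until the center shift falls below ``tol``.  The
    threshold is the midpoint of the converged centers.  Deterministic.
    """
    unmasked = (
        np.ones(img.geometry.shape, dtype=bool) if exclude is None else ~exclude.pixels
    )
    values = img.pixels[unmasked]
    if values.size == 0 or np.unique(values).size < 2:
        raise ValueError("degenerate intensity distribution (<2 distinct values)")
    lo, hi = values.min(), values.max()
    counts, edges = np.histogram(values, bins=bins, range=(lo, hi))
    mids = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    init = (np.percentile(values, 10.0), np.percentile(values, 90.0))
    if init[0] == init[1]:
        init = (float(lo), float(hi))
    centers, iters, converged = _fcm_1d(
        mids[keep], counts[keep].astype(np.float64), init, max_iter, tol
    )
    threshold = float(centers.mean())
    return ThresholdResult(
        threshold=threshold,
        cluster_centers=(float(centers[0]), float(centers[1])),
        iterations=iters,
        converged=converged,
    )


# --------------------------------------------------------------------------
# binarization and size filtering


def binarize_flow(
    flow: EnFaceImage, thr: ThresholdResult, exclude: BinaryMask | None = None
) -> FlowDeficitMap:
    """Deficit iff unmasked and intensity below the threshold."""
    deficits = flow.pixels < thr.threshold
    if exclude is not None:
        if exclude.geometry.shape != flow.geometry.shape:
            raise ValueError("exclude mask geometry mismatch")
        deficits &= ~exclude.pixels
    return FlowDeficitMap(deficits, flow.geometry, thr, min_gld_um=0.0)


_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connectivity


def component_gld_um(coords: np.ndarray, spacing_um: float) -> float:
    """Greatest linear dimension of a connected component.

    Defined as the maximum pairwise Euclidean distance between pixel
    centers, converted to µm, plus one pixel spacing — so a single pixel
    has GLD equal to the spacing.
    """
    n = coords.shape[0]
    if n == 1:
        return spacing_um
    pts = coords.astype(np.float64)
    if n > 300:
        # the diameter is attained on the convex hull
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # collinear; brute force below
    return float(pdist(pts).max() * spacing_um + spacing_um)


def filter_small_deficits(fd: FlowDeficitMap, min_gld_um: float = 24.0) -> FlowDeficitMap:
    """Remove deficits with greatest linear dimension below ``min_gld_um``.

    Connected components use 8-connectivity; components with
    GLD < min_gld_um (strict) are removed, all others kept intact.
    Idempotent; never adds deficits.
    """
    spacing = fd.geometry.pixel_spacing_um
    labels, n = ndimage.label(fd.pixels, structure=_STRUCT8)
    keep = fd.pixels.copy()
    for sl, lab in zip(ndimage.find_objects(labels), range(1, n + 1)):
        comp = labels[sl] == lab
        coords = np.argwhere(comp)
        if component_gld_um(coords, spacing) < min_gld_um:
            region = keep[sl]
            region[comp] = False
    return FlowDeficitMap(keep, fd.geometry, fd.source_threshold, min_gld_um)


# --------------------------------------------------------------------------
# full per-scan pipeline


def quantify_scan(
    flow: EnFaceImage,
    structure: EnFaceImage,
    retina: EnFaceImage | None,
    masks: list[BinaryMask],
    cfg: QuantConfig = QuantConfig(),
) -> tuple[FlowDeficitMap, BinaryMask]:
    """Run the per-scan quantification chain and return the filtered
    flow-deficit map together with the combined exclusion mask that was
    actually applied.

    Stage order: merge lesion masks -> compensate flow -> add the retinal
    vessel-projection mask -> FCM threshold on the compensated flow ->
    binarize -> GLD filter.
    """
    geometry = flow.geometry
    combined = np.zeros(geometry.shape, dtype=bool)
    for m in masks:
        if m.geometry.shape != geometry.shape:
            raise ValueError("mask geometry mismatch in quantify_scan")
        combined |= m.pixels
    combined_mask = BinaryMask(combined, geometry, MaskKind.COMBINED)

    stage = "compensation"
    try:
        comp = compensate_flow(flow, structure, cfg.compensation, combined_mask)
        stage = "vessel projection mask"
        if retina is not None:
            vessel = derive_vessel_projection_mask(
                retina,
                threshold=cfg.vessel_threshold,
                dilation_px=cfg.vessel_dilation_px,
            )
            combined_mask = BinaryMask(
                combined_mask.pixels | vessel.pixels, geometry, MaskKind.COMBINED
            )
        stage = "FCM threshold"
        thr = fcm_threshold(comp, combined_mask, cfg.fcm_max_iter, cfg.fcm_tol)
        stage = "binarization"
        fd = binarize_flow(comp, thr, combined_mask)
        stage = "GLD filter"
        fd = filter_small_deficits(fd, cfg.min_gld_um)
    except ValueError as exc:
        raise ValueError(f"quantify_scan failed at stage '{stage}': {exc}") from exc
    return fd, combined_mask
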