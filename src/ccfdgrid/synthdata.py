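"""Synthetic en-face OCTA eyes with known ground truth.

Generates 500x500-px, 12-µm-spacing en-face scan sets (CC flow, CC
structure, retinal vasculature) with:

* a true flow-deficit field built from thresholded correlated noise, whose
  blob scale matches the choriocapillaris intercapillary distance so the
  24-µm GLD filter and the global threshold see realistic size structure;
* drusen rendered as smooth-edged discs of multiplicative signal
  attenuation shared by the flow and structure channels — the regime in
  which structure-based compensation is exact;
* lesion exclusion masks (HRF-like blobs);
* a recursive branching vessel tree on the retinal channel providing
  landmarks for registration;
* repeat scans (same truth, independent noise, random rigid misalignment)
  and longitudinal drusen-resolution pairs (the target druse's attenuation
  removed at follow-up while the true deficit field is unchanged).

Everything is deterministic given the configuration and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .align_grid import RigidTransform, apply_transform
from .scan_io import (
    BinaryMask,
    Channel,
    EnFaceImage,
    GroupLabel,
    MaskKind,
    ScanGeometry,
    ScanMetadata,
)

__all__ = [
    "DrusenSpec",
    "LesionSpec",
    "SimulationConfig",
    "SyntheticEyeTruth",
    "ScanBundle",
    "simulate_eye",
    "simulate_repeats",
    "simulate_drusen_resolution_pair",
    "true_ccfd_percent",
]


@dataclass(frozen=True)
class DrusenSpec:
    """One druse: center (row, col) px, radius µm, and the multiplicative
    attenuation it applies to both flow and structure (1 = no attenuation)."""

    center_px: tuple[float, float]
    radius_um: float
    attenuation_factor: float = 0.5
    druse_id: str = "druse"

    def __post_init__(self):
        if not (0.0 < self.attenuation_factor <= 1.0):
            raise ValueError("attenuation_factor must be in (0, 1]")
        if self.radius_um <= 0:
            raise ValueError("radius_um must be positive")


@dataclass(frozen=True)
class LesionSpec:
    kind: MaskKind
    center_px: tuple[float, float]
    radius_um: float


def _default_drusen() -> tuple[DrusenSpec, ...]:
    # an iAMD-like load: three large drusen, ~6% of the scan area, one of
    # which (druse_0) is the resolving target in longitudinal fixtures
    return (
        DrusenSpec((170.0, 170.0), 420.0, 0.5, "druse_0"),
        DrusenSpec((330.0, 310.0), 480.0, 0.5, "druse_1"),
        DrusenSpec((160.0, 360.0), 540.0, 0.5, "druse_2"),
    )


def _default_lesions() -> tuple[LesionSpec, ...]:
    return (
        LesionSpec(MaskKind.HRF, (100.0, 250.0), 90.0),
        LesionSpec(MaskKind.HRF, (400.0, 120.0), 110.0),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition defaults: 500x500 px at 12 µm (nominal 6x6 mm),
    ~8% flow-deficit fraction at the CC intercapillary scale, three
    same-day repeats with modest noise and up to ±8 px misalignment."""

    size_px: int = 500
    pixel_spacing_um: float = 12.0
    fd_density: float = 0.08
    fd_blob_scale_um: float = 36.0
    fd_contrast: float = 0.55
    flow_base: float = 120.0
    structure_base: float = 150.0
    noise_sd: float = 5.0
    drusen: tuple[DrusenSpec, ...] = field(default_factory=_default_drusen)
    lesions: tuple[LesionSpec, ...] = field(default_factory=_default_lesions)
    vessel_n_trunks: int = 6
    vessel_depth: int = 5
    repeat_noise_sd: float = 4.0
    misalignment_max_px: int = 8
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.fd_density < 0.5):
            raise ValueError("fd_density must be in (0, 0.5)")
        if self.fd_blob_scale_um <= 0 or self.pixel_spacing_um <= 0:
            raise ValueError("scales must be positive")

    @property
    def geometry(self) -> ScanGeometry:
        return ScanGeometry.create(self.size_px, self.size_px, self.pixel_spacing_um)


@dataclass
class SyntheticEyeTruth:
    true_fd_map: np.ndarray  # bool
    attenuation_field: np.ndarray
    mask_truths: dict[str, np.ndarray]
    fovea_px: tuple[float, float]
    config: SimulationConfig

    def true_ccfd_fraction(self, roi: np.ndarray | None = None) -> float:
        sel = np.ones_like(self.true_fd_map) if roi is None else roi
        return float(self.true_fd_map[sel].mean())


@dataclass
class ScanBundle:
    """One acquired scan: the three en-face channels, lesion masks, and the
    true rigid misalignment applied (identity for the baseline repeat)."""

    flow: EnFaceImage
    structure: EnFaceImage
    retina: EnFaceImage
    masks: list[BinaryMask]
    metadata: ScanMetadata
    true_shift: RigidTransform


def true_ccfd_percent(truth: SyntheticEyeTruth, roi: np.ndarray | None = None) -> float:
    """Ground-truth CCFD% over an ROI by the pixel-count rule."""
    return 100.0 * truth.true_ccfd_fraction(roi)


# --------------------------------------------------------------------------
# field builders


def _fd_field(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Thresholded correlated Gaussian noise with correlation length
    ``fd_blob_scale_um``; the threshold quantile fixes the deficit fraction
    exactly (up to ties, absent for continuous noise)."""
    sigma_px = cfg.fd_blob_scale_um / cfg.pixel_spacing_um
    noise = ndimage.gaussian_filter(
        rng.standard_normal((cfg.size_px, cfg.size_px)), sigma=sigma_px
    )
    cut = np.quantile(noise, cfg.fd_density)
    return noise <= cut


def _smooth_disc(
    shape: tuple[int, int], center: tuple[float, float], radius_px: float, edge_px: float = 3.0
) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    dist = np.sqrt((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
    disc = (dist <= radius_px).astype(np.float64)
    return ndimage.gaussian_filter(disc, sigma=edge_px)


def _attenuation_field(
    cfg: SimulationConfig, drusen: tuple[DrusenSpec, ...]
) -> np.ndarray:
    att = np.ones((cfg.size_px, cfg.size_px))
    for d in drusen:
        profile = _smooth_disc(
            att.shape, d.center_px, d.radius_um / cfg.pixel_spacing_um
        )
        att *= 1.0 - (1.0 - d.attenuation_factor) * profile
    return att


def _vessel_canvas(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Recursive branching tree rendered as Gaussian-profile curves —
    landmarks for registration, not a physiological vascular model."""
    size = cfg.size_px
    canvas = np.zeros((size, size))

    def draw_segment(p0, angle, length, width):
        n = max(int(length), 2)
        ts = np.linspace(0.0, length, n)
        rows = p0[0] + ts * math.sin(angle)
        cols = p0[1] + ts * math.cos(angle)
        ok = (rows >= 0) & (rows < size) & (cols >= 0) & (cols < size)
        canvas[rows[ok].astype(int), cols[ok].astype(int)] = np.maximum(
            canvas[rows[ok].astype(int), cols[ok].astype(int)], width
        )
        return (p0[0] + length * math.sin(angle), p0[1] + length * math.cos(angle))

    def branch(p0, angle, length, width, depth):
        if depth == 0 or width < 0.5:
            return
        p1 = draw_segment(p0, angle, length, width)
        n_children = 2 if rng.random() < 0.8 else 1
        for _ in range(n_children):
            branch(
                p1,
                angle + rng.uniform(-0.7, 0.7),
                length * rng.uniform(0.6, 0.85),
                width * rng.uniform(0.6, 0.9),
                depth - 1,
            )

    center = (size / 2.0, size / 2.0)
    for k in range(cfg.vessel_n_trunks):
        theta = 2.0 * math.pi * k / cfg.vessel_n_trunks + rng.uniform(-0.3, 0.3)
        start = (
            center[0] + 0.46 * size * math.sin(theta),
            center[1] + 0.46 * size * math.cos(theta),
        )
        branch(start, theta + math.pi, size * rng.uniform(0.22, 0.3), 4.0, cfg.vessel_depth)

    blurred = ndimage.gaussian_filter(canvas, sigma=1.5)
    if blurred.max() > 0:
        blurred = blurred / blurred.max()
    return 20.0 + 200.0 * blurred


def _lesion_masks(
    cfg: SimulationConfig, geometry: ScanGeometry
) -> tuple[list[BinaryMask], dict[str, np.ndarray]]:
    masks: list[BinaryMask] = []
    truths: dict[str, np.ndarray] = {}
    for i, les in enumerate(cfg.lesions):
        rr, cc = np.ogrid[: cfg.size_px, : cfg.size_px]
        dist = np.sqrt((rr - les.center_px[0]) ** 2 + (cc - les.center_px[1]) ** 2)
        px = dist <= les.radius_um / cfg.pixel_spacing_um
        masks.append(BinaryMask(px, geometry, les.kind))
        truths[f"{les.kind.value}_{i}"] = px
    return masks, truths


# --------------------------------------------------------------------------
# public generators


def _render_channels(
    truth: SyntheticEyeTruth,
    cfg: SimulationConfig,
    vessels: np.ndarray,
    rng: np.random.Generator,
    extra_noise_sd: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sd = math.hypot(cfg.noise_sd, extra_noise_sd)
    att = truth.attenuation_field
    fd = truth.true_fd_map
    flow = cfg.flow_base * (1.0 - fd * cfg.fd_contrast) * att
    flow = flow + sd * rng.standard_normal(flow.shape)
    structure = cfg.structure_base * att + sd * rng.standard_normal(flow.shape)
    retina = vessels + sd * rng.standard_normal(flow.shape)
    return (np.clip(flow, 0, None), np.clip(structure, 0, None), np.clip(retina, 0, None))


def simulate_eye(
    cfg: SimulationConfig = SimulationConfig(),
    metadata: ScanMetadata | None = None,
) -> tuple[EnFaceImage, EnFaceImage, EnFaceImage, list[BinaryMask], SyntheticEyeTruth]:
    """Generate one synthetic eye: (flow, structure, retina, lesion masks,
    ground truth).  Deterministic given ``cfg`` (including its seed)."""
    rng = np.random.default_rng(cfg.seed)
    geometry = cfg.geometry
    fd = _fd_field(cfg, rng)
    att = _attenuation_field(cfg, cfg.drusen)
    vessels = _vessel_canvas(cfg, rng)
    masks, mask_truths = _lesion_masks(cfg, geometry)
    truth = SyntheticEyeTruth(fd, att, mask_truths, geometry.fovea_px, cfg)
    flow_px, struct_px, retina_px = _render_channels(truth, cfg, vessels, rng)
    meta = metadata or ScanMetadata("P000", "E000", "V000")
    flow = EnFaceImage(flow_px, geometry, Channel.CC_FLOW, meta)
    structure = EnFaceImage(struct_px, geometry, Channel.CC_STRUCTURE, meta)
    retina = EnFaceImage(retina_px, geometry, Channel.RETINAL_VASCULATURE, meta)
    truth._vessels = vessels  # cached for repeat rendering
    return flow, structure, retina, masks, truth


def _shift_bundle(
    flow_px, struct_px, retina_px, masks, geometry, shift: RigidTransform, meta
) -> ScanBundle:
    def mv(px, channel):
        img = EnFaceImage(px, geometry, channel, meta)
        if shift.is_identity:
            return img
        moved, _ = apply_transform(img, shift)
        return moved

    moved_masks = []
    for m in masks:
        if shift.is_identity:
            moved_masks.append(m)
        else:
            mm, _ = apply_transform(m, shift)
            moved_masks.append(mm)
    return ScanBundle(
        flow=mv(flow_px, Channel.CC_FLOW),
        structure=mv(struct_px, Channel.CC_STRUCTURE),
        retina=mv(retina_px, Channel.RETINAL_VASCULATURE),
        masks=moved_masks,
        metadata=meta,
        true_shift=shift,
    )


def simulate_repeats(
    truth: SyntheticEyeTruth,
    n: int = 3,
    cfg: SimulationConfig | None = None,
    seed: int | None = None,
    metadata: ScanMetadata | None = None,
) -> list[ScanBundle]:
    """Same-day repeat scans of one eye: identical truth, independent
    acquisition noise (``repeat_noise_sd``) and a random integer rigid
    misalignment per repeat (the first repeat is the reference, identity)."""
    if n < 2:
        raise ValueError("need n >= 2 repeats")
    cfg = cfg or truth.config
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    geometry = cfg.geometry
    vessels = getattr(truth, "_vessels", None)
    if vessels is None:
        vessels = _vessel_canvas(cfg, np.random.default_rng(cfg.seed))
    base_meta = metadata or ScanMetadata("P000", "E000", "V000")
    masks, _ = _lesion_masks(cfg, geometry)
    out = []
    for rep in range(1, n + 1):
        flow_px, struct_px, retina_px = _render_channels(
            truth, cfg, vessels, rng, extra_noise_sd=cfg.repeat_noise_sd
        )
        if rep == 1 or cfg.misalignment_max_px == 0:
            shift = RigidTransform(0, 0, 0.0, score=1.0)
        else:
            m = cfg.misalignment_max_px
            shift = RigidTransform(
                int(rng.integers(-m, m + 1)), int(rng.integers(-m, m + 1)), 0.0
            )
        meta = ScanMetadata(
            base_meta.patient_id,
            base_meta.eye_id,
            base_meta.visit_id,
            repeat_index=rep,
            signal_strength=base_meta.signal_strength,
            group_label=base_meta.group_label,
        )
        out.append(
            _shift_bundle(flow_px, struct_px, retina_px, masks, geometry, shift, meta)
        )
    return out


def simulate_drusen_resolution_pair(
    truth: SyntheticEyeTruth,
    druse_id: str = "druse_0",
    cfg: SimulationConfig | None = None,
    seed: int | None = None,
) -> tuple[ScanBundle, ScanBundle, tuple[float, float]]:
    """Baseline/follow-up scan pair in which one druse resolves without
    sequelae: its attenuation disappears at follow-up while the true
    deficit field is unchanged.  Returns (baseline, followup,
    target_center_px) with the resolving druse's center for grid targeting.
    """
    cfg = cfg or truth.config
    target = next((d for d in cfg.drusen if d.druse_id == druse_id), None)
    if target is None:
        raise ValueError(f"unknown druse_id: {druse_id}")
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    geometry = cfg.geometry
    vessels = getattr(truth, "_vessels", None)
    if vessels is None:
        vessels = _vessel_canvas(cfg, np.random.default_rng(cfg.seed))
    masks, _ = _lesion_masks(cfg, geometry)

    remaining = tuple(d for d in cfg.drusen if d.druse_id != druse_id)
    truth_followup = SyntheticEyeTruth(
        truth.true_fd_map,
        _attenuation_field(cfg, remaining),
        truth.mask_truths,
        truth.fovea_px,
        cfg,
    )

    bundles = []
    for visit, (tr, shift_allowed) in enumerate(
        [(truth, False), (truth_followup, True)]
    ):
        flow_px, struct_px, retina_px = _render_channels(
            tr, cfg, vessels, rng, extra_noise_sd=cfg.repeat_noise_sd
        )
        if shift_allowed and cfg.misalignment_max_px > 0:
            m = cfg.misalignment_max_px
            shift = RigidTransform(
                int(rng.integers(-m, m + 1)), int(rng.integers(-m, m + 1)), 0.0
            )
        else:
            shift = RigidTransform(0, 0, 0.0, score=1.0)
        meta = ScanMetadata("P000", "E000", f"V{visit:03d}", repeat_index=1)
        bundles.append(
            _shift_bundle(flow_px, struct_px, retina_px, masks, geometry, shift, meta)
        )
    return bundles[0], bundles[1], target.center_px
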