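import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist

from ccfdgrid import (
    BinaryMask,
    CC_SLAB,
    Channel,
    CompensationConfig,
    EnFaceImage,
    FlowDeficitMap,
    QuantConfig,
    ScanGeometry,
    SlabDefinition,
    ThresholdResult,
    VolumeScan,
    binarize_flow,
    compensate_flow,
    compute_ccfd_percent,
    derive_vessel_projection_mask,
    fcm_threshold,
    filter_small_deficits,
    quantify_scan,
)

from conftest import make_image


# --------------------------------------------------------------------------
# slab extraction


def brute_force_slab(vol: VolumeScan, slab: SlabDefinition, channel):
    """Voxel-loop oracle: include voxel d iff offset <= (d-bm)*dz < offset+thick."""
    vox = vol.flow_voxels if channel == Channel.CC_FLOW else vol.structure_voxels
    h, w, nd = vox.shape
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            vals = [
                vox[r, c, d]
                for d in range(nd)
                if slab.offset_start_um
                <= (d - vol.bm_surface_px[r, c]) * vol.axial_spacing_um
                < slab.offset_start_um + slab.thickness_um
            ]
            out[r, c] = max(vals) if slab.projection == "max" else np.mean(vals)
    return out


def make_volume(rng, h=8, w=8, depth=32, dz=2.0):
    vol = rng.random((h, w, depth))
    bm = rng.integers(0, depth - 12, (h, w))
    g = ScanGeometry.create(w, h, 12.0)
    return VolumeScan(vol, vol * 2 + 1, dz, bm, g)


class TestExtractSlab:
    def test_constant_volume_projects_to_constant(self):
        g = ScanGeometry.create(4, 4, 12.0)
        vol = VolumeScan(np.full((4, 4, 20), 3.5), np.full((4, 4, 20), 3.5), 2.0,
                         np.zeros((4, 4), dtype=int), g)
        from ccfdgrid import extract_slab

        img = extract_slab(vol, CC_SLAB, Channel.CC_FLOW)
        assert np.allclose(img.pixels, 3.5)

    def test_cc_slab_uses_eight_voxels_at_2um(self):
        """Offset 4 µm / thickness 16 µm at 2 µm axial spacing selects depth
        indices bm+2 .. bm+9 inclusive."""
        from ccfdgrid import extract_slab

        g = ScanGeometry.create(1, 1, 12.0)
        vox = np.zeros((1, 1, 20))
        vox[0, 0, 2:10] = 8.0  # bm = 0
        vol = VolumeScan(vox, vox, 2.0, np.zeros((1, 1), dtype=int), g)
        img = extract_slab(vol, CC_SLAB, Channel.CC_FLOW)
        assert img.pixels[0, 0] == pytest.approx(8.0)  # all 8 in-slab voxels bright
        vox2 = np.zeros((1, 1, 20))
        vox2[0, 0, 1] = 8.0  # just above the slab
        vox2[0, 0, 10] = 8.0  # just below the slab
        vol2 = VolumeScan(vox2, vox2, 2.0, np.zeros((1, 1), dtype=int), g)
        assert extract_slab(vol2, CC_SLAB, Channel.CC_FLOW).pixels[0, 0] == 0.0

    @pytest.mark.parametrize("projection", ["mean", "max"])
    def test_matches_voxel_loop_oracle(self, projection):
        from ccfdgrid import extract_slab

        rng = np.random.default_rng(5)
        vol = make_volume(rng)
        slab = SlabDefinition(4.0, 16.0, projection)
        img = extract_slab(vol, slab, Channel.CC_FLOW)
        assert np.array_equal(img.pixels, brute_force_slab(vol, slab, Channel.CC_FLOW))

    def test_single_bright_voxel_mean(self):
        from ccfdgrid import extract_slab

        g = ScanGeometry.create(3, 3, 12.0)
        vox = np.zeros((3, 3, 20))
        bm = np.full((3, 3), 2, dtype=int)
        vox[1, 1, 2 + 4] = 16.0  # inside [bm+2, bm+10)
        vol = VolumeScan(vox, vox, 2.0, bm, g)
        img = extract_slab(vol, CC_SLAB, Channel.CC_FLOW)
        expected = np.zeros((3, 3))
        expected[1, 1] = 16.0 / 8.0
        assert np.array_equal(img.pixels, expected)

    def test_slab_past_depth_names_pixel(self):
        from ccfdgrid import extract_slab

        g = ScanGeometry.create(2, 2, 12.0)
        bm = np.array([[0, 0], [0, 8]])
        vol = VolumeScan(np.zeros((2, 2, 12)), np.zeros((2, 2, 12)), 2.0, bm, g)
        with pytest.raises(ValueError, match=r"row=1, col=1"):
            extract_slab(vol, CC_SLAB, Channel.CC_FLOW)


# --------------------------------------------------------------------------
# compensation


class TestCompensation:
    def test_constant_structure_is_noop_up_to_scale(self):
        rng = np.random.default_rng(0)
        flow = make_image(rng.uniform(50, 150, (64, 64)))
        structure = make_image(np.full((64, 64), 140.0))
        comp = compensate_flow(flow, structure)
        assert np.allclose(comp.pixels, flow.pixels, rtol=1e-10)

    def test_recovers_shared_multiplicative_attenuation(self):
        """flow_obs = flow*A, structure_obs = structure*A with A=0.5 in a
        disc: divide-mode compensation restores the disc to within 5%."""
        rng = np.random.default_rng(1)
        h = w = 128
        rr, cc = np.ogrid[:h, :w]
        disc = (rr - 64) ** 2 + (cc - 64) ** 2 <= 30**2
        A = np.where(disc, 0.5, 1.0)
        flow_true = np.full((h, w), 100.0)
        comp = compensate_flow(
            make_image(flow_true * A),
            make_image(np.full((h, w), 150.0) * A),
            CompensationConfig(floor_quantile=0.0),
        )
        interior = (rr - 64) ** 2 + (cc - 64) ** 2 <= 20**2  # away from the edge
        outside = ~((rr - 64) ** 2 + (cc - 64) ** 2 <= 40**2)
        assert np.abs(comp.pixels[interior] - comp.pixels[outside].mean()).max() < 5.0

    def test_all_zero_structure_rejected(self):
        flow = make_image(np.ones((8, 8)))
        with pytest.raises(ValueError, match="degenerate structure"):
            compensate_flow(flow, make_image(np.zeros((8, 8))))

    def test_off_mode_returns_copy(self):
        flow = make_image(np.arange(64.0).reshape(8, 8))
        out = compensate_flow(flow, make_image(np.ones((8, 8))), CompensationConfig(mode="off"))
        assert np.array_equal(out.pixels, flow.pixels)
        assert out.pixels is not flow.pixels

    def test_complement_mode_brightens_shadowed_region(self):
        rng = np.random.default_rng(2)
        h = w = 96
        rr, cc = np.ogrid[:h, :w]
        disc = (rr - 48) ** 2 + (cc - 48) ** 2 <= 20**2
        A = np.where(disc, 0.5, 1.0)
        flow = make_image(100.0 * A + rng.normal(0, 1, (h, w)).clip(-3, 3) + 5)
        structure = make_image(150.0 * A)
        comp = compensate_flow(flow, structure, CompensationConfig(mode="complement"))
        # shadowed disc raised relative to its uncompensated level
        assert comp.pixels[disc].mean() > flow.pixels[disc].mean()


# --------------------------------------------------------------------------
# vessel projection mask


class TestVesselMask:
    def test_all_zero_image_gives_empty_mask(self):
        m = derive_vessel_projection_mask(make_image(np.zeros((32, 32))))
        assert m.count_true == 0

    def test_two_level_strip_matches_hand_mask(self):
        px = np.full((40, 40), 10.0)
        px[18:21, :] = 200.0
        m = derive_vessel_projection_mask(make_image(px), dilation_px=1)
        from scipy.ndimage import binary_dilation
        from skimage.morphology import disk

        expected = binary_dilation(px > 100, structure=disk(1))
        assert np.array_equal(m.pixels, expected)

    def test_monotone_in_intensity(self):
        rng = np.random.default_rng(3)
        px = rng.uniform(0, 100, (32, 32))
        m1 = derive_vessel_projection_mask(make_image(px), threshold=50.0, dilation_px=0)
        px2 = px.copy()
        px2[4, 4] = 99.0
        m2 = derive_vessel_projection_mask(make_image(px2), threshold=50.0, dilation_px=0)
        assert np.all(m2.pixels >= m1.pixels)


# --------------------------------------------------------------------------
# fuzzy C-means threshold


def unbinned_fcm(values, max_iter=500, tol=1e-9):
    """Oracle: 2-cluster FCM (m=2) on the raw pixel values, no histogram."""
    centers = np.percentile(values, [10.0, 90.0]).astype(float)
    for _ in range(max_iter):
        d2 = np.maximum((values[:, None] - centers[None, :]) ** 2, 1e-300)
        u = (1.0 / d2) / (1.0 / d2).sum(axis=1, keepdims=True)
        new = ((u**2) * values[:, None]).sum(axis=0) / (u**2).sum(axis=0)
        if np.abs(new - centers).max() < tol:
            centers = new
            break
        centers = new
    centers = np.sort(centers)
    return centers.mean()


class TestFCM:
    def test_two_equal_populations_midpoint(self):
        px = np.tile(np.array([10.0, 100.0]), (10, 50))
        t = fcm_threshold(make_image(px))
        assert t.threshold == pytest.approx(55.0)
        assert t.converged

    def test_matches_unbinned_oracle_on_mixture(self):
        rng = np.random.default_rng(17)
        values = np.concatenate(
            [rng.normal(20, 5, 5000), rng.normal(120, 15, 5000)]
        ).clip(0)
        t = fcm_threshold(make_image(values.reshape(100, 100)))
        assert abs(t.threshold - unbinned_fcm(values)) < 2.0

    @given(st.floats(min_value=0.0, max_value=500.0))
    @settings(max_examples=20, deadline=None)
    def test_translation_equivariance(self, c):
        rng = np.random.default_rng(23)
        px = np.concatenate([rng.normal(30, 4, 800), rng.normal(90, 6, 800)]).clip(0)
        px = px.reshape(40, 40)
        t0 = fcm_threshold(make_image(px))
        t1 = fcm_threshold(make_image(px + c))
        assert t1.threshold == pytest.approx(t0.threshold + c, abs=1e-6)

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(ValueError, match="degenerate intensity"):
            fcm_threshold(make_image(np.full((8, 8), 7.0)))

    def test_masked_pixels_ignored(self):
        px = np.tile(np.array([10.0, 100.0]), (10, 50))
        px[0, :10] = 5000.0  # masked outlier
        g = make_image(px)
        exclude = BinaryMask(px == 5000.0, g.geometry)
        t = fcm_threshold(g, exclude)
        assert t.threshold == pytest.approx(55.0)


# --------------------------------------------------------------------------
# binarization and GLD filter


def brute_force_gld_filter(pixels, spacing, min_gld):
    """Enumerate 8-connected components and all pixel pairs."""
    from scipy import ndimage

    labels, n = ndimage.label(pixels, structure=np.ones((3, 3)))
    out = pixels.copy()
    for lab in range(1, n + 1):
        coords = np.argwhere(labels == lab).astype(float)
        if len(coords) == 1:
            gld = spacing
        else:
            gld = pdist(coords).max() * spacing + spacing
        if gld < min_gld:
            out[labels == lab] = False
    return out


class TestBinarizeAndFilter:
    def test_no_deficits_when_all_above_threshold(self):
        thr = ThresholdResult(50.0, (10.0, 90.0), 5, True)
        fd = binarize_flow(make_image(np.full((8, 8), 60.0)), thr)
        assert fd.count_true == 0

    def test_threshold_splits_two_values(self):
        thr = ThresholdResult(55.0, (10.0, 100.0), 5, True)
        px = np.tile(np.array([10.0, 100.0]), (4, 4))
        fd = binarize_flow(make_image(px), thr)
        assert np.array_equal(fd.pixels, px == 10.0)

    def test_masked_pixel_never_deficit(self):
        thr = ThresholdResult(55.0, (10.0, 100.0), 5, True)
        img = make_image(np.full((8, 8), 10.0))
        mask = BinaryMask(np.eye(8, dtype=bool), img.geometry)
        fd = binarize_flow(img, thr, mask)
        assert not fd.pixels[np.eye(8, dtype=bool)].any()
        assert fd.pixels[~np.eye(8, dtype=bool)].all()

    def test_single_pixel_removed_at_12um(self):
        px = np.zeros((10, 10), dtype=bool)
        px[5, 5] = True
        fd = FlowDeficitMap(px, ScanGeometry.create(10, 10, 12.0))
        out = filter_small_deficits(fd, 24.0)
        assert out.count_true == 0  # GLD 12 um < 24

    def test_two_adjacent_pixels_kept_at_12um(self):
        px = np.zeros((10, 10), dtype=bool)
        px[5, 5:7] = True  # GLD = 12 + 12 = 24, not < 24
        fd = FlowDeficitMap(px, ScanGeometry.create(10, 10, 12.0))
        out = filter_small_deficits(fd, 24.0)
        assert out.count_true == 2

    def test_matches_brute_force_oracle_on_random_map(self):
        rng = np.random.default_rng(11)
        px = rng.random((64, 64)) < 0.15
        fd = FlowDeficitMap(px, ScanGeometry.create(64, 64, 12.0))
        out = filter_small_deficits(fd, 40.0)
        assert np.array_equal(out.pixels, brute_force_gld_filter(px, 12.0, 40.0))

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_idempotent_and_never_adds(self, seed):
        rng = np.random.default_rng(seed)
        px = rng.random((40, 40)) < 0.12
        fd = FlowDeficitMap(px, ScanGeometry.create(40, 40, 12.0))
        once = filter_small_deficits(fd, 24.0)
        twice = filter_small_deficits(once, 24.0)
        assert np.array_equal(once.pixels, twice.pixels)
        assert not (once.pixels & ~px).any()


# --------------------------------------------------------------------------
# full per-scan pipeline


class TestQuantifyScan:
    def test_agrees_with_generator_truth_without_lesions(self, plain_eye):
        flow, structure, retina, masks, truth = plain_eye
        fd, combined = quantify_scan(flow, structure, retina, masks)
        whole = BinaryMask.full(flow.geometry)
        m = compute_ccfd_percent(fd, combined, whole)
        assert abs(m.ccfd_percent - 100.0 * truth.true_ccfd_fraction()) < 2.0

    def test_compensation_lowers_ccfd_on_shadowed_eye(self, drusen_eye):
        (flow, structure, retina, masks, truth), _ = drusen_eye
        whole = BinaryMask.full(flow.geometry)
        res = {}
        for mode in ("off", "divide"):
            cfg = QuantConfig(compensation=CompensationConfig(mode=mode))
            fd, combined = quantify_scan(flow, structure, retina, masks, cfg)
            res[mode] = compute_ccfd_percent(fd, combined, whole).ccfd_percent
        assert res["off"] > res["divide"]

    def test_deterministic(self, plain_eye):
        flow, structure, retina, masks, _ = plain_eye
        fd1, c1 = quantify_scan(flow, structure, retina, masks)
        fd2, c2 = quantify_scan(flow, structure, retina, masks)
        assert np.array_equal(fd1.pixels, fd2.pixels)
        assert np.array_equal(c1.pixels, c2.pixels)

    def test_deficits_subset_of_unmasked(self, drusen_eye):
        (flow, structure, retina, masks, _), _ = drusen_eye
        fd, combined = quantify_scan(flow, structure, retina, masks)
        assert not (fd.pixels & combined.pixels).any()

    def test_stage_error_names_stage(self, plain_eye):
        flow, structure, retina, masks, _ = plain_eye
        zero_struct = structure.with_pixels(np.zeros_like(structure.pixels))
        with pytest.raises(ValueError, match="compensation"):
            quantify_scan(flow, zero_struct, retina, masks)
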