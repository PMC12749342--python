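"""Registration stages: rescaling, PCC, matching, affine refinement, warping."""

import numpy as np
import pytest

import clxmreg as cx
from clxmreg.errors import DegenerateGeometryError, InputError
from clxmreg.register import RefineOptions, match_pairs
from clxmreg.segment import CentroidSet
from clxmreg.synthetic import RenderParams


def points_set(pts):
    return CentroidSet(np.asarray(pts, float))


def disc_mask(points_px, shape=(256, 256), radius_px=4, pixel_nm=29.0):
    """Synthetic SegmentationMask with small discs at given (col,row) pixels."""
    labels = np.zeros(shape, int)
    yy, xx = np.indices(shape)
    for k, (cx_, cy_) in enumerate(points_px, start=1):
        labels[(xx - cx_) ** 2 + (yy - cy_) ** 2 <= radius_px ** 2] = k
    return cx.mask_from_labels(labels, pixel_nm)


class TestRescale:
    def test_fm_to_sxt_pitch_shape(self):
        img = cx.ImagePlane(np.zeros((100, 100)), 120.0)
        out = cx.rescale_to_reference(img, 29.0)
        assert out.pixel_size_nm == 29.0
        assert out.shape == (414, 414)  # 100 * 120/29 ~ 413.8

    def test_same_pitch_is_identity(self):
        img = cx.ImagePlane(np.random.default_rng(0).normal(size=(32, 32)), 29.0)
        out = cx.rescale_to_reference(img, 29.0)
        assert out is img or np.array_equal(out.pixels, img.pixels)

    def test_constant_stays_constant_and_range_preserved(self):
        img = cx.ImagePlane(np.full((50, 50), 7.25), 120.0)
        out = cx.rescale_to_reference(img, 29.0)
        assert np.allclose(out.pixels, 7.25)

    def test_physical_positions_preserved(self):
        """A feature at a known physical position stays there after rescale."""
        img = np.zeros((100, 100))
        img[40, 60] = 1.0  # at (60*120, 40*120) nm
        out = cx.rescale_to_reference(cx.ImagePlane(img, 120.0), 29.0)
        r, c = np.unravel_index(np.argmax(out.pixels), out.shape)
        assert abs(c * 29.0 - 60 * 120.0) <= 29.0
        assert abs(r * 29.0 - 40 * 120.0) <= 29.0


class TestCoarsePCC:
    def test_identical_masks_give_zero(self):
        m = disc_mask([(60, 50), (180, 90), (120, 200)])
        dx, dy = cx.coarse_align_pcc(m, m)
        assert abs(dx) < 14.5 and abs(dy) < 14.5  # < 0.5 px

    def test_rolled_mask_recovered(self):
        ref = disc_mask([(60, 50), (180, 90), (120, 200), (40, 160)])
        mov_labels = np.roll(ref.labels, shift=(3, -5), axis=(0, 1))
        mov = cx.mask_from_labels(mov_labels, 29.0)
        # moving features sit at ref + (dx=-5, dy=+3) px; mov->ref = (+5, -3) px
        dx, dy = cx.coarse_align_pcc(ref, mov)
        assert dx == pytest.approx(5 * 29.0, abs=0.5 * 29.0)
        assert dy == pytest.approx(-3 * 29.0, abs=0.5 * 29.0)

    def test_single_pixel_masks_analytic_peak(self):
        ref = np.zeros((64, 64), int)
        mov = np.zeros((64, 64), int)
        ref[20, 30] = 1
        mov[24, 21] = 1
        dx, dy = cx.coarse_align_pcc(cx.mask_from_labels(ref, 29.0),
                                     cx.mask_from_labels(mov, 29.0))
        assert dx == pytest.approx((30 - 21) * 29.0, abs=0.5 * 29.0)
        assert dy == pytest.approx((20 - 24) * 29.0, abs=0.5 * 29.0)

    def test_empty_mask_rejected(self):
        m = disc_mask([(60, 50)])
        empty = cx.mask_from_labels(np.zeros((64, 64), int), 29.0)
        with pytest.raises(InputError):
            cx.coarse_align_pcc(m, empty)

    def test_pixel_size_mismatch_rejected(self):
        with pytest.raises(InputError):
            cx.coarse_align_pcc(disc_mask([(50, 50)], pixel_nm=29.0),
                                disc_mask([(50, 50)], pixel_nm=120.0))


class TestMatchPairs:
    def test_identity_perfect_pairing(self):
        pts = np.random.default_rng(0).uniform(0, 10000, (8, 2))
        pairs = match_pairs(points_set(pts), points_set(pts), None, 500.0)
        assert len(pairs) == 8
        assert np.allclose(pairs.distances_nm, 0.0)

    def test_uniform_offset_within_gate(self):
        pts = np.random.default_rng(1).uniform(0, 10000, (10, 2))
        pairs = match_pairs(points_set(pts), points_set(pts - [100.0, 0.0]), None, 500.0)
        assert len(pairs) == 10
        assert np.allclose(pairs.distances_nm, 100.0)

    def test_outlier_beyond_gate_excluded(self):
        ref = np.array([[0.0, 0.0], [1000.0, 0.0], [0.0, 1000.0]])
        mov = np.vstack([ref, [[5000.0, 5000.0]]])
        pairs = match_pairs(points_set(ref), points_set(mov), None, 500.0)
        assert len(pairs) == 3
        assert 3 not in pairs.mov_idx

    def test_one_to_one(self):
        ref = np.array([[0.0, 0.0], [100.0, 0.0]])
        mov = np.array([[10.0, 0.0], [12.0, 0.0], [90.0, 0.0]])
        pairs = match_pairs(points_set(ref), points_set(mov), None, 500.0)
        assert len(np.unique(pairs.ref_idx)) == len(pairs)
        assert len(np.unique(pairs.mov_idx)) == len(pairs)


class TestRefineAffine:
    def test_identity_recovered_from_identical_sets(self):
        pts = np.random.default_rng(2).uniform(0, 20000, (10, 2))
        a = cx.refine_affine(points_set(pts), points_set(pts), init=(0.0, 0.0))
        assert np.hypot(a.tx_nm, a.ty_nm) < 1.0
        assert abs(a.theta_deg) < 0.01
        assert abs(a.sx - 1) < 1e-4 and abs(a.sy - 1) < 1e-4

    def test_forward_generated_affine_recovered(self):
        rng = np.random.default_rng(3)
        ref = rng.uniform(2000, 28000, (12, 2))
        centre = tuple(ref.mean(axis=0))
        true = cx.AffineTransform2D(300.0, -150.0, 2.0, 1.02, 0.98, centre)
        mov = true.inverse().apply(ref)  # so that true maps mov -> ref
        a = cx.refine_affine(points_set(ref), points_set(mov), init=(0.0, 0.0))
        # compare by action on the landmark set
        assert np.allclose(a.apply(mov), ref, atol=1.0)
        assert a.theta_deg == pytest.approx(2.0, abs=2e-3)
        assert a.sx == pytest.approx(1.02, rel=1e-3)
        assert a.sy == pytest.approx(0.98, rel=1e-3)

    def test_two_points_degenerate(self):
        pts = np.array([[0.0, 0.0], [1000.0, 1000.0]])
        with pytest.raises(DegenerateGeometryError):
            cx.refine_affine(points_set(pts), points_set(pts))

    def test_no_gated_pairs_degenerate(self):
        ref = np.random.default_rng(4).uniform(0, 1000, (5, 2))
        mov = ref + 50000.0
        with pytest.raises(DegenerateGeometryError):
            cx.refine_affine(points_set(ref), points_set(mov), init=(0.0, 0.0))


class TestApply:
    def test_identity_leaves_image_unchanged(self):
        img = cx.ImagePlane(np.random.default_rng(5).normal(size=(40, 40)), 29.0)
        out = cx.apply_to_image(img, cx.AffineTransform2D())
        assert np.allclose(out.pixels, img.pixels, atol=1e-9)

    def test_translation_moves_impulse(self):
        img = np.zeros((64, 64))
        img[30, 20] = 1.0
        a = cx.AffineTransform2D(tx_nm=5 * 29.0, ty_nm=-3 * 29.0)
        out = cx.apply_to_image(cx.ImagePlane(img, 29.0), a)
        r, c = np.unravel_index(np.argmax(out.pixels), out.shape)
        assert (r, c) == (27, 25)

    def test_points_forward_then_inverse(self):
        a = cx.AffineTransform2D(123.0, -45.0, 3.0, 1.05, 0.95, (500.0, 700.0))
        pts = np.random.default_rng(6).uniform(-5000, 5000, (20, 2))
        back = a.inverse().apply(cx.apply_to_points(pts, a))
        assert np.allclose(back, pts, atol=1e-6)


class TestOverlay:
    def test_disjoint_signals_pure_channels(self):
        ref = np.zeros((32, 32))
        ref[5:10, 5:10] = 1.0  # absorbing feature (dark in SXT convention)
        mov = np.zeros((32, 32))
        mov[20:25, 20:25] = 1.0
        ov = cx.compose_overlay(
            cx.ImagePlane(1.0 - ref, 29.0, cx.Modality.SXT),  # droplets dark
            cx.ImagePlane(mov, 29.0, cx.Modality.FM))
        assert ov.pixels[7, 7, 0] == 255 and ov.pixels[7, 7, 2] == 0
        assert ov.pixels[22, 22, 2] == 255 and ov.pixels[22, 22, 0] == 0

    def test_identical_images_grayscale(self):
        x = np.random.default_rng(7).uniform(0, 1, (16, 16))
        ov = cx.compose_overlay(cx.ImagePlane(x, 29.0, cx.Modality.OTHER),
                                cx.ImagePlane(x, 29.0, cx.Modality.OTHER))
        assert np.array_equal(ov.pixels[..., 0], ov.pixels[..., 1])
        assert np.array_equal(ov.pixels[..., 1], ov.pixels[..., 2])

    def test_grid_mismatch_rejected(self):
        with pytest.raises(InputError):
            cx.compose_overlay(cx.ImagePlane(np.zeros((8, 8)), 29.0),
                               cx.ImagePlane(np.zeros((9, 8)), 29.0))


class TestRegisterPair:
    def test_self_registration_is_identity(self, pair_cache):
        _, sxt, _, _ = pair_cache(1)
        res = cx.register_pair(sxt, sxt, make_overlay=False)
        a = res.affine
        assert np.hypot(a.tx_nm, a.ty_nm) < 1.0
        assert abs(a.theta_deg) < 0.01
        assert abs(a.sx - 1) < 1e-4 and abs(a.sy - 1) < 1e-4
        assert np.allclose(res.residuals_before_nm, 0.0, atol=1e-6)

    def test_affine_only_scene_registered_under_one_sxt_pixel(self, pair_cache):
        fm, sxt, scene, gt = pair_cache(2, noise=False, with_warp=False)
        res = cx.register_pair(sxt, fm, make_overlay=False)
        assert res.residuals_before_nm.mean() < 29.0

    def test_warped_scene_residual_zero_at_controls(self, pair_cache):
        fm, sxt, scene, gt = pair_cache(3, noise=False, with_warp=True)
        res = cx.register_pair(sxt, fm)
        assert np.allclose(res.residuals_after_nm, 0.0, atol=1e-6)
        assert res.overlay is not None
        assert res.overlay.pixels.shape == (*sxt.shape, 3)

    def test_translation_equivariance(self, pair_cache):
        """Shifting both images by the same physical offset leaves the
        estimated linear part unchanged and the translation consistent."""
        fm, sxt, scene, gt = pair_cache(2, noise=False, with_warp=False)
        res0 = cx.register_pair(sxt, fm, make_overlay=False)
        shift_px = 10  # shift both rasters identically
        fm2 = fm.with_pixels(np.roll(fm.pixels, shift_px, axis=1))
        sxt2 = sxt.with_pixels(np.roll(sxt.pixels, round(shift_px * fm.pixel_size_nm
                                                         / sxt.pixel_size_nm), axis=1))
        res1 = cx.register_pair(sxt2, fm2, make_overlay=False)
        assert res1.affine.theta_deg == pytest.approx(res0.affine.theta_deg, abs=0.05)
        assert res1.affine.sx == pytest.approx(res0.affine.sx, abs=5e-3)
        assert res1.affine.sy == pytest.approx(res0.affine.sy, abs=5e-3)
        # same physical displacement at matched landmarks
        c = res0.ref_centroids.points_nm.mean(axis=0)
        shift_nm = round(shift_px * fm.pixel_size_nm / sxt.pixel_size_nm) * sxt.pixel_size_nm
        d0 = res0.affine.apply(c)[0] - c
        d1 = res1.affine.apply(c + shift_nm * np.array([1.0, 0.0]))[0] - (c + shift_nm * np.array([1.0, 0.0]))
        assert np.allclose(d0, d1, atol=29.0)

    def test_refined_cost_not_worse_than_coarse(self, pair_cache):
        for seed in (1, 2, 3):
            fm, sxt, scene, gt = pair_cache(seed)
            res = cx.register_pair(sxt, fm, make_overlay=False)
            ref_c, mov_c = res.ref_centroids, res.mov_centroids
            gate = 2000.0
            coarse_pairs = match_pairs(ref_c, mov_c, np.asarray(res.coarse_shift_nm), gate)
            refined_pairs = match_pairs(ref_c, mov_c, res.affine, gate)
            assert np.mean(refined_pairs.distances_nm ** 2) <= np.mean(
                coarse_pairs.distances_nm ** 2) + 1e-9
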