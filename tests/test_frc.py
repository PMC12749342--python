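"""Fourier ring correlation, frame splitting, depth profile, FWHM."""

import numpy as np
import pytest

import clxmreg as cx
from clxmreg.errors import InputError
from clxmreg.frc import FRCCurve


def plane(data, px=29.0):
    return cx.ImagePlane(np.asarray(data, float), px)


def noise_img(seed, n=128, px=29.0):
    return plane(np.random.default_rng(seed).normal(size=(n, n)), px)


def bandlimited_pair(kc_bins, n=256, snr=20.0, seed=0, px=29.0):
    """Shared signal with a hard Fourier cutoff at kc_bins + independent noise."""
    rng = np.random.default_rng(seed)
    spec = rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
    yy, xx = np.indices((n, n))
    r = np.hypot(yy - n // 2, xx - n // 2)
    spec[r >= kc_bins] = 0  # cutoff aligned with a ring boundary
    base = np.fft.ifft2(np.fft.ifftshift(spec)).real
    base *= snr / base.std()
    a = base + rng.normal(size=(n, n))
    b = base + rng.normal(size=(n, n))
    return plane(a, px), plane(b, px)


class TestSplitFrames:
    def test_four_identical_frames_sum_to_2v(self):
        frames = cx.ImageStack([cx.ImagePlane(np.full((8, 8), 3.0), 29.0)] * 4)
        a, b = cx.split_frames(frames)
        assert len(a) == len(b) == 1
        assert np.all(a[0].pixels == 6.0) and np.all(b[0].pixels == 6.0)

    def test_signal_conservation(self):
        data = np.random.default_rng(0).uniform(0, 10, (6, 16, 16))
        frames = cx.ImageStack([cx.ImagePlane(d, 29.0) for d in data])
        a, b = cx.split_frames(frames, frames_per_tilt=2)
        total = a.as_array() + b.as_array()
        assert np.allclose(total, data.reshape(3, 2, 16, 16).sum(axis=1))

    def test_odd_frames_per_tilt_rejected(self):
        frames = cx.ImageStack([cx.ImagePlane(np.zeros((4, 4)), 29.0)] * 3)
        with pytest.raises(InputError):
            cx.split_frames(frames)
        with pytest.raises(InputError):
            cx.split_frames(cx.ImageStack([cx.ImagePlane(np.zeros((4, 4)), 29.0)] * 6),
                            frames_per_tilt=3)


class TestFRC:
    def test_self_correlation_is_unity(self):
        img = noise_img(1)
        curve = cx.frc(img, img)
        assert np.allclose(curve.frc, 1.0, atol=1e-9)

    def test_symmetric_in_arguments(self):
        a, b = noise_img(2), noise_img(3)
        ca, cb = cx.frc(a, b), cx.frc(b, a)
        assert np.array_equal(ca.frc, cb.frc)

    def test_independent_noise_near_zero(self):
        a, b = noise_img(4, n=256), noise_img(5, n=256)
        curve = cx.frc(a, b)
        # sampling-theory bound on the ring-averaged correlation of noise
        bound = 3.0 / np.sqrt(np.sum(curve.ring_counts))
        assert abs(np.mean(curve.frc[1:])) < max(bound, 0.02)

    def test_affine_intensity_rescaling_invariance(self):
        a, b = bandlimited_pair(40, seed=6)
        c1 = cx.frc(a, b)
        c2 = cx.frc(a, plane(2.5 * b.pixels - 7.0, b.pixel_size_nm))
        assert np.allclose(c1.frc, c2.frc, atol=1e-9)

    def test_band_structure_high_below_cutoff(self):
        a, b = bandlimited_pair(50, n=256, seed=7)
        curve = cx.frc(a, b, window="none")
        n = 256
        inside = curve.frc[2: int(50 * 0.8)]
        outside = curve.frc[int(50 * 1.3): n // 2 - 2]
        assert inside.mean() > 0.8
        assert abs(outside.mean()) < 0.1

    def test_frequency_axis_up_to_nyquist(self):
        img = noise_img(8, n=64, px=29.0)
        curve = cx.frc(img, img)
        assert np.all(np.diff(curve.spatial_frequency) > 0)
        assert curve.spatial_frequency[-1] <= 1 / (2 * 29.0) * 1.01

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InputError):
            cx.frc(plane(np.zeros((8, 8))), plane(np.zeros((9, 9))))


class TestResolutionAtThreshold:
    def test_hand_interpolated_crossing(self):
        """Linear interpolation between rings at (0.01, 0.30) and
        (0.0125, 0.20): the 0.25 level sits halfway, so the crossing is at
        0.01 + 0.0025·(0.30−0.25)/(0.30−0.20) = 0.01125 cyc/nm,
        a full pitch of 1/0.01125 ≈ 88.9 nm."""
        curve = FRCCurve(
            spatial_frequency=np.array([0.0, 0.005, 0.01, 0.0125, 0.015]),
            frc=np.array([1.0, 0.8, 0.3, 0.2, 0.1]),
            ring_counts=np.ones(5, int), pixel_size_nm=29.0)
        est = cx.resolution_at_threshold(curve, threshold=0.25)
        assert est.crossing_frequency == pytest.approx(0.01125)
        assert est.full_pitch_nm == pytest.approx(1 / 0.01125, rel=1e-6)
        assert est.full_pitch_nm == pytest.approx(88.9, abs=0.05)
        assert est.interpolated

    def test_default_threshold_is_quarter(self):
        import inspect
        sig = inspect.signature(cx.resolution_at_threshold)
        assert sig.parameters["threshold"].default == 0.25

    def test_no_crossing_is_nyquist_limited(self):
        img = noise_img(9)
        est = cx.resolution_at_threshold(cx.frc(img, img))
        assert est.status == "nyquist"
        assert est.full_pitch_nm == pytest.approx(2 * 29.0)

    def test_all_below_threshold_is_degenerate(self):
        curve = FRCCurve(
            spatial_frequency=np.array([0.0, 0.005, 0.01, 0.015]),
            frc=np.array([1.0, 0.1, 0.05, 0.02]),
            ring_counts=np.ones(4, int), pixel_size_nm=29.0)
        est = cx.resolution_at_threshold(curve)
        assert est.status == "degenerate"
        assert np.isnan(est.full_pitch_nm)

    def test_band_limit_recovered_within_one_ring(self):
        kc = 60
        n = 256
        a, b = bandlimited_pair(kc, n=n, snr=50.0, seed=12)
        curve = cx.frc(a, b, window="none")
        est = cx.resolution_at_threshold(curve, threshold=0.25)
        ring_width = 1.0 / (n * a.pixel_size_nm)
        analytic = kc / (n * a.pixel_size_nm)
        assert abs(est.crossing_frequency - analytic) <= ring_width


class TestDepthProfile:
    def test_identical_stacks_all_nyquist(self):
        sl = [noise_img(s, n=64) for s in range(3)]
        stack = cx.ImageStack(sl)
        prof = cx.depth_profile(stack, stack)
        assert len(prof) == 3
        assert all(p == pytest.approx(2 * 29.0) for _, p in prof)

    def test_z_dependent_blur_degrades_resolution_away_from_focus(self):
        from scipy.ndimage import gaussian_filter
        rng = np.random.default_rng(13)
        base = rng.normal(size=(256, 256))
        base *= 30 / base.std()
        slices_a, slices_b = [], []
        for sigma in (0.0, 1.5, 3.0):  # focal slice first
            s = gaussian_filter(base, sigma) if sigma else base
            slices_a.append(plane(s + rng.normal(size=s.shape)))
            slices_b.append(plane(s + rng.normal(size=s.shape)))
        prof = cx.depth_profile(cx.ImageStack(slices_a), cx.ImageStack(slices_b))
        pitches = [p for _, p in prof]
        assert pitches[0] == min(pitches)
        assert pitches[0] <= pitches[1] <= pitches[2] * 1.05
        assert prof[0][0] == 0.0  # focal slice at zero offset

    def test_slice_count_mismatch_rejected(self):
        a = cx.ImageStack([noise_img(1)])
        b = cx.ImageStack([noise_img(1), noise_img(2)])
        with pytest.raises(InputError):
            cx.depth_profile(a, b)


class TestLineProfileFWHM:
    def gaussian_peak_image(self, sigma_nm=20.0, px=2.0, n=201):
        xs = (np.arange(n) - n // 2) * px
        row = np.exp(-xs ** 2 / (2 * sigma_nm ** 2))
        return cx.ImagePlane(np.tile(row, (n, 1)), px)

    def test_gaussian_fwhm_closed_form(self):
        img = self.gaussian_peak_image()
        centre = (img.shape[1] // 2) * img.pixel_size_nm
        prof = cx.line_profile(img, (0.0, centre), (2 * centre, centre), step_nm=1.0)
        width = cx.fwhm(prof)
        assert width == pytest.approx(2 * np.sqrt(2 * np.log(2)) * 20.0, abs=0.5)

    def test_rectangular_dip_width(self):
        n, px = 201, 2.0
        row = np.ones(n)
        centre = n // 2
        half_w_px = int(30 / px)
        row[centre - half_w_px: centre + half_w_px] = 0.0  # 60 nm dip
        img = cx.ImagePlane(np.tile(row, (5, 1)), px)
        prof = cx.line_profile(img, (0.0, 2 * px), ((n - 1) * px, 2 * px), step_nm=1.0)
        assert cx.fwhm(prof, polarity="dip") == pytest.approx(60.0, abs=1.5)

    def test_monotone_ramp_has_no_fwhm(self):
        img = cx.ImagePlane(np.tile(np.linspace(0, 1, 101), (5, 1)), 2.0)
        prof = cx.line_profile(img, (0.0, 4.0), (200.0, 4.0), step_nm=1.0)
        with pytest.raises(InputError):
            cx.fwhm(prof)

    def test_fwhm_converges_with_step(self):
        img = self.gaussian_peak_image()
        centre = (img.shape[1] // 2) * img.pixel_size_nm
        truth = 2 * np.sqrt(2 * np.log(2)) * 20.0
        errs = []
        for step in (4.0, 0.5):
            prof = cx.line_profile(img, (0.0, centre), (2 * centre, centre), step)
            errs.append(abs(cx.fwhm(prof) - truth))
        assert errs[1] <= errs[0]

    def test_profile_positions_uniform_and_inside(self):
        img = self.gaussian_peak_image()
        prof = cx.line_profile(img, (10.0, 10.0), (110.0, 10.0), step_nm=5.0)
        assert np.allclose(np.diff(prof.positions_nm), 5.0)
        with pytest.raises(InputError):
            cx.line_profile(img, (-5.0, 0.0), (10.0, 0.0), step_nm=1.0)
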