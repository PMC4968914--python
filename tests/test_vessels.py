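"""Vessel detection: Phansalkar threshold (closed form + brute force),
Frangi vesselness properties, binarization."""

import numpy as np
import pytest

import omagflux as og
from omagflux.vessels import phansalkar_threshold


def enface(pixels, scale=0.02):
    return og.EnFaceImage(pixels=pixels, mm_per_pixel=(scale, scale))


def brute_force_phansalkar(img, params):
    """Independent per-pixel loop with symmetric (reflected) padding."""
    half = params.window // 2
    padded = np.pad(img, half, mode="symmetric")
    out = np.zeros(img.shape, dtype=bool)
    for y in range(img.shape[0]):
        for x in range(img.shape[1]):
            win = padded[y : y + params.window, x : x + params.window]
            m = win.mean()
            s = win.std()
            t = m * (1 + params.p * np.exp(-params.q * m) + params.k * (s / params.r - 1))
            out[y, x] = img[y, x] < t
    return out


class TestPhansalkar:
    def test_uniform_image_closed_form(self):
        """Constant image m=0.8: T = 0.8(1 + 2e^-9.6 - 0.135) ~ 0.692 -> empty mask."""
        img = np.full((32, 32), 0.8)
        params = og.PhansalkarParams()
        thr = phansalkar_threshold(img, params)
        expected = 0.8 * (1 + 2.0 * np.exp(-9.6) + 0.135 * (0 / 0.5 - 1))
        # separable mean/variance filters leave ~1e-8 round-off in s
        np.testing.assert_allclose(thr, expected, rtol=1e-6)
        assert expected < 0.8
        mask = og.phansalkar_mask(enface(img), params)
        assert not mask.mask.any()

    def test_matches_brute_force_on_random_images(self, rng):
        params = og.PhansalkarParams(window=9)
        for _ in range(20):
            img = rng.uniform(0, 1, (32, 32))
            fast = og.phansalkar_mask(enface(img), params).mask
            np.testing.assert_array_equal(fast, brute_force_phansalkar(img, params))

    def test_window_larger_than_image_via_reflection(self, rng):
        """61x61 window on a 64x64 image still equals the brute-force loop."""
        img = rng.uniform(0, 1, (64, 64))
        params = og.PhansalkarParams(window=61)
        fast = og.phansalkar_mask(enface(img), params).mask
        np.testing.assert_array_equal(fast, brute_force_phansalkar(img, params))

    def test_shadow_stripes_detected(self):
        """0.4x-background shadow stripes: >= 95% hit rate, <= 2% false alarms."""
        scene = og.flat_scene(
            shape=(64, 64, 64), big_vessel_count=2, shadow_attenuation=0.4,
            lateral_extent_mm=4.8, noise_sigma=0.05, seed=4,
        )
        cube, truth = og.generate_cube(scene)
        vol = og.compute_flow(og.compensate_bulk_phase(cube))
        lb = og.segment_layers(vol.structure)
        img = og.project_rpe_structure(vol.amplitude(), lb, mm_per_pixel=(0.075, 0.075))
        norm = og.EnFaceImage(
            pixels=img.pixels / img.pixels.max(), mm_per_pixel=img.mm_per_pixel, valid=img.valid
        )
        mask = og.phansalkar_mask(norm).mask
        hit = mask[truth.big_vessel_mask].mean()
        fp = mask[~truth.big_vessel_mask].mean()
        assert hit >= 0.95
        assert fp <= 0.02

    def test_unnormalized_input_refused(self):
        with pytest.raises(ValueError, match="normalized"):
            og.phansalkar_mask(enface(np.full((8, 8), 3.0)))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError, match="window"):
            og.PhansalkarParams(window=8)
        with pytest.raises(ValueError, match="r must"):
            og.PhansalkarParams(r=0.0)


def gaussian_ridge(shape, width, angle_deg=0.0, amplitude=1.0):
    """1-D Gaussian ridge of the given width through the image center."""
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2, (nx - 1) / 2
    t = np.deg2rad(angle_deg)
    d = -(xx - cx) * np.sin(t) + (yy - cy) * np.cos(t)
    return amplitude * np.exp(-(d**2) / (2 * width**2))


class TestFrangi:
    def test_constant_image_zero_vesselness(self):
        v = og.frangi_vesselness(enface(np.full((32, 32), 0.5)), scales=(1, 2))
        np.testing.assert_array_equal(v.pixels, 0.0)

    def test_ridge_scores_above_blob(self):
        """An isotropic blob scores below an equal-amplitude ridge."""
        yy, xx = np.mgrid[0:33, 0:33]
        blob = np.exp(-((yy - 16) ** 2 + (xx - 16) ** 2) / (2 * 2.0**2))
        ridge = gaussian_ridge((33, 33), 2.0)
        c_fixed = 1.0
        v_blob = og.frangi_vesselness(enface(blob), scales=(2.0,), c=c_fixed).pixels[16, 16]
        v_ridge = og.frangi_vesselness(enface(ridge), scales=(2.0,), c=c_fixed).pixels[16, 16]
        assert v_ridge > v_blob

    def test_scale_selection_tracks_ridge_width(self):
        """For a Gaussian ridge of width w the sigma^2-normalized center
        response is sigma^2 w / (w^2 + sigma^2)^(3/2), maximized at
        sigma = sqrt(2) w; the measured argmax should match that closed form."""
        for width in (1.5, 3.0):
            scales = np.geomspace(0.5, 10.0, 25)
            ridge = gaussian_ridge((65, 65), width)
            responses = [
                og.frangi_vesselness(enface(ridge), scales=(s,), c=1.0).pixels[32, 32]
                for s in scales
            ]
            best = scales[int(np.argmax(responses))]
            assert best == pytest.approx(np.sqrt(2) * width, rel=0.2)

    def test_rotation_invariance_within_five_percent(self):
        peaks = []
        for ang in (0, 30, 60, 90, 120, 150):
            ridge = gaussian_ridge((65, 65), 2.0, angle_deg=ang)
            v = og.frangi_vesselness(enface(ridge), scales=(2.0,), c=1.0)
            peaks.append(v.pixels[30:35, 30:35].max())
        assert (max(peaks) - min(peaks)) / max(peaks) <= 0.05

    def test_additive_offset_invariance_and_contrast_monotonicity(self):
        ridge = gaussian_ridge((33, 33), 2.0)
        v0 = og.frangi_vesselness(enface(ridge), scales=(2.0,), c=1.0).pixels
        v_shift = og.frangi_vesselness(enface(ridge + 5.0), scales=(2.0,), c=1.0).pixels
        np.testing.assert_allclose(v_shift, v0, atol=1e-9)
        v_double = og.frangi_vesselness(enface(2 * ridge), scales=(2.0,), c=1.0).pixels
        assert v_double[16, 16] >= v0[16, 16]

    def test_empty_scales_refused(self):
        with pytest.raises(ValueError, match="scale"):
            og.frangi_vesselness(enface(np.ones((8, 8))), scales=())

    def test_against_skimage_reference_ordering(self):
        """Sanity cross-check: rank correlation with the scikit-image filter."""
        from skimage.filters import frangi as sk_frangi

        rng = np.random.default_rng(5)
        img = gaussian_ridge((49, 49), 2.0) + 0.05 * rng.standard_normal((49, 49))
        mine = og.frangi_vesselness(enface(img), scales=(1.0, 2.0, 3.0)).pixels
        ref = sk_frangi(img, sigmas=(1.0, 2.0, 3.0), black_ridges=False)
        from scipy.stats import spearmanr

        rho, _ = spearmanr(mine.ravel(), ref.ravel())
        assert rho > 0.8


class TestBinarize:
    def test_all_zero_empty_mask(self):
        m = og.binarize_vessels(enface(np.zeros((16, 16))))
        assert not m.mask.any()

    def test_two_level_image_separates(self):
        img = np.zeros((16, 16))
        img[4:12, 6:9] = 1.0
        m = og.binarize_vessels(enface(img), min_size=1)
        np.testing.assert_array_equal(m.mask, img == 1.0)

    def test_small_components_removed(self):
        img = np.zeros((32, 32))
        img[2, 2] = 1.0  # single speckle pixel
        img[10:20, 5] = 1.0  # a real vessel segment
        m = og.binarize_vessels(enface(img), min_size=5)
        assert not m.mask[2, 2]
        assert m.mask[10:20, 5].all()
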