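"""Unit and property tests for the segmentation chain, stage by stage.

Every numeric stage is checked against an independent brute-force oracle
(double-loop convolution, double-loop rank filters, analytic geometry) so
regressions in the vectorised implementations cannot hide.
"""

import numpy as np
import pytest

from conftest import brute_force_correlate, brute_force_rank
from cytosizer import (
    Contour,
    GaussianKernelSpec,
    GrayImage,
    InvalidInputError,
    InvalidParameterError,
    NoParticleError,
    OpticsSpec,
    ParticleSpec,
    SegmentationConfig,
    canny_edges,
    estimate_shape,
    find_particle_contour,
    gaussian_blur,
    gaussian_kernel,
    measure_pixels,
    morph_dilate,
    morph_erode,
    preprocess,
    render_frame,
)


class TestPreprocess:
    def test_identity_when_already_target_size(self):
        img = np.random.default_rng(0).integers(0, 256, (120, 120)).astype(float)
        out = preprocess(img)
        assert out.scale_factor == (1.0, 1.0)
        np.testing.assert_array_equal(out.pixels, img)

    def test_downscale_records_per_axis_factors(self):
        out = preprocess(np.zeros((240, 240), dtype=np.uint8))
        assert out.pixels.shape == (120, 120)
        assert out.scale_factor == (2.0, 2.0)

    def test_nonsquare_disk_diameter_recovered_via_axis_factors(self):
        # oracle: pixel-count equivalent diameter of the rendered mask
        optics = OpticsSpec(blur_sigma_px=0, noise_sigma=0, frame_side_px=240)
        frame = render_frame(ParticleSpec.circle(60 * 0.33, center_jitter_px=0),
                             optics, seed=0)
        img = np.vstack([frame.image, np.full((120, 240), frame.image[0, 0])])  # 360x240
        true_d = 2 * np.sqrt(frame.mask.sum() / np.pi)
        out = preprocess(img)
        assert out.pixels.shape == (120, 120)
        assert out.scale_factor == (3.0, 2.0)
        # the dark disk survives resizing; measure its extent per axis and map back
        dark = out.pixels < (out.pixels.min() + out.pixels.max()) / 2
        rows, cols = np.nonzero(dark)
        h = (rows.max() - rows.min() + 1) * out.scale_factor[0]
        w = (cols.max() - cols.min() + 1) * out.scale_factor[1]
        assert h == pytest.approx(true_d, abs=3.0)
        assert w == pytest.approx(true_d, abs=2.0)

    def test_rgb_collapsed_by_luminance(self):
        rgb = np.zeros((120, 120, 3), dtype=np.uint8)
        rgb[..., 1] = 100  # green only
        out = preprocess(rgb)
        assert out.pixels[0, 0] == pytest.approx(58.7)

    def test_empty_image_rejected(self):
        with pytest.raises(InvalidInputError):
            preprocess(np.zeros((0, 0)))


class TestGaussianBlur:
    def test_kernel_is_unit_sum_and_peaked_at_centre(self):
        k = gaussian_kernel(GaussianKernelSpec(size=5, sigma_i=1.4, sigma_j=1.4))
        assert k.sum() == pytest.approx(1.0)
        assert k[2, 2] == k.max()

    def test_even_kernel_size_rejected(self):
        with pytest.raises(InvalidParameterError):
            GaussianKernelSpec(size=4)

    def test_constant_raster_preserved(self):
        img = GrayImage(np.full((20, 20), 37.0))
        np.testing.assert_allclose(gaussian_blur(img).pixels, 37.0)

    def test_impulse_response_is_the_kernel(self):
        img = np.zeros((9, 9))
        img[4, 4] = 1.0
        spec = GaussianKernelSpec(size=3, sigma_i=1.0, sigma_j=1.0)
        out = gaussian_blur(GrayImage(img), spec).pixels
        np.testing.assert_allclose(out[3:6, 3:6], gaussian_kernel(spec), atol=1e-12)

    def test_matches_double_loop_convolution_oracle(self):
        rng = np.random.default_rng(42)
        img = rng.uniform(0, 255, (16, 16))
        spec = GaussianKernelSpec(size=5, sigma_i=1.4, sigma_j=0.9)
        out = gaussian_blur(GrayImage(img), spec).pixels
        oracle = brute_force_correlate(img, gaussian_kernel(spec))
        np.testing.assert_allclose(out, oracle, atol=1e-9)

    def test_interior_mean_conserved(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 255, (40, 40))
        out = gaussian_blur(GrayImage(img)).pixels
        # away from borders a unit-sum kernel redistributes, never creates, mass
        assert out[5:-5, 5:-5].mean() == pytest.approx(img[5:-5, 5:-5].mean(), rel=1e-3)
        assert out.sum() == pytest.approx(img.sum(), rel=1e-6)  # reflect border conserves


class TestCanny:
    def test_constant_image_has_no_edges(self):
        out = canny_edges(GrayImage(np.full((30, 30), 90.0)))
        assert out.pixels.sum() == 0

    def test_vertical_step_yields_single_pixel_line(self):
        img = np.zeros((20, 20))
        img[:, 10:] = 200.0
        out = canny_edges(GrayImage(img), low=50, high=150)
        cols = np.nonzero(out.pixels.any(axis=0))[0]
        assert len(cols) == 1  # non-maximum suppression thins the step to 1 px
        assert cols[0] in (9, 10)
        assert out.pixels[:, cols[0]].all()

    def test_disk_edges_lie_on_analytic_circle(self, clean_optics):
        frame = render_frame(ParticleSpec.circle(40 * 0.33, center_jitter_px=0),
                             clean_optics, seed=0)
        blurred = gaussian_blur(preprocess(frame.image_u8))
        edges = canny_edges(blurred).pixels
        ys, xs = np.nonzero(edges)
        cx, cy = frame.center_px
        r = np.hypot(xs - cx, ys - cy)
        assert len(r) > 40
        assert np.all(np.abs(r - 20.0) <= 2.0)

    def test_low_above_high_rejected(self):
        with pytest.raises(InvalidParameterError):
            canny_edges(GrayImage(np.zeros((5, 5))), low=10, high=5)


class TestMorphology:
    def test_zero_iterations_is_identity(self):
        img = np.random.default_rng(0).integers(0, 2, (10, 10))
        np.testing.assert_array_equal(morph_erode(img, 3, 0), img)
        np.testing.assert_array_equal(morph_dilate(img, 3, 0), img)

    def test_erode_peels_one_pixel_ring(self):
        mask = np.zeros((12, 12), dtype=np.uint8)
        mask[3:9, 3:9] = 1
        out = morph_erode(mask, 3, 1)
        expected = np.zeros_like(mask)
        expected[4:8, 4:8] = 1
        np.testing.assert_array_equal(out, expected)

    def test_single_pixel_dilates_to_full_kernel_block(self):
        mask = np.zeros((9, 9), dtype=np.uint8)
        mask[4, 4] = 1
        out = morph_dilate(mask, 3, 1)
        assert out[3:6, 3:6].all() and out.sum() == 9

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_rank_filter_oracle_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.integers(0, 2, (12, 12)).astype(np.uint8)
        np.testing.assert_array_equal(morph_erode(mask, 3, 1),
                                      brute_force_rank(mask, 3, np.min))
        np.testing.assert_array_equal(morph_dilate(mask, 3, 1),
                                      brute_force_rank(mask, 3, np.max))

    @pytest.mark.parametrize("seed", range(5))
    def test_opening_and_closing_ordering(self, seed):
        rng = np.random.default_rng(seed)
        mask = (rng.random((16, 16)) < 0.4).astype(np.uint8)
        opening = morph_dilate(morph_erode(mask, 3, 1), 3, 1)
        closing = morph_erode(morph_dilate(mask, 3, 1), 3, 1)
        assert opening.sum() <= mask.sum() <= closing.sum()
        assert np.all(opening <= mask) and np.all(mask <= closing)


class TestFindContour:
    def test_square_boundary_encloses_square_area(self):
        mask = np.zeros((120, 120), dtype=np.uint8)
        mask[50:70, 50:70] = 1
        contour = find_particle_contour(mask)
        from cytosizer import contour_to_mask
        area = contour_to_mask(contour, mask.shape).sum()
        assert area == pytest.approx(400, abs=80)  # boundary convention slack

    def test_largest_component_wins_over_speck(self):
        mask = np.zeros((120, 120), dtype=np.uint8)
        mask[40:65, 40:60] = 1  # 500 px blob
        mask[10:16, 10:15] = 1  # 30 px speck
        contour = find_particle_contour(mask, min_area=20)
        assert contour.points[:, 0].min() > 30  # speck untouched

    def test_disk_contour_area_matches_pixel_count(self):
        mask = np.zeros((120, 120), dtype=np.uint8)
        yy, xx = np.mgrid[:120, :120]
        mask[(yy - 60) ** 2 + (xx - 60) ** 2 <= 30**2] = 1
        contour = find_particle_contour(mask)
        from cytosizer import contour_to_mask
        assert contour_to_mask(contour, mask.shape).sum() == pytest.approx(
            mask.sum(), rel=0.05)

    def test_empty_mask_raises(self):
        with pytest.raises(NoParticleError):
            find_particle_contour(np.zeros((50, 50), dtype=np.uint8))

    def test_all_speck_mask_raises(self):
        mask = np.zeros((50, 50), dtype=np.uint8)
        mask[10:13, 10:13] = 1
        with pytest.raises(NoParticleError):
            find_particle_contour(mask, min_area=20)


def _ellipse_points(a, b, angle_deg=0.0, center=(60, 60), n=60):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    x, y = a * np.cos(t), b * np.sin(t)
    rad = np.deg2rad(angle_deg)
    return np.column_stack([
        center[0] + x * np.cos(rad) - y * np.sin(rad),
        center[1] + x * np.sin(rad) + y * np.cos(rad),
    ])


class TestEstimateShape:
    def test_axis_aligned_ellipse_axes_recovered(self):
        shape = estimate_shape(Contour(_ellipse_points(20, 10)))
        assert shape.height_px == pytest.approx(40, rel=0.02)
        assert shape.width_px == pytest.approx(20, rel=0.02)

    def test_circle_has_equal_height_and_width(self):
        shape = estimate_shape(Contour(_ellipse_points(15, 15)))
        assert shape.height_px == pytest.approx(shape.width_px, rel=0.02)
        assert shape.height_px == pytest.approx(30, rel=0.02)

    def test_rotation_leaves_axes_invariant(self):
        base = estimate_shape(Contour(_ellipse_points(20, 10)))
        rot = estimate_shape(Contour(_ellipse_points(20, 10, angle_deg=30)))
        assert rot.height_px == pytest.approx(base.height_px, rel=0.02)
        assert rot.width_px == pytest.approx(base.width_px, rel=0.02)
        assert rot.angle_deg == pytest.approx(30, abs=2)

    def test_scale_factor_maps_back_to_original_pixels(self):
        shape = estimate_shape(Contour(_ellipse_points(20, 10)), scale_factor=(2.0, 3.0))
        # x stretched by 3, y by 2: major axis (x-aligned, 40 px) -> 120 px
        assert shape.height_px == pytest.approx(120, rel=0.02)
        assert shape.width_px == pytest.approx(40, rel=0.02)

    def test_four_points_fall_back_to_rotated_rectangle(self):
        quad = Contour(np.array([[0.0, 0.0], [8.0, 0.0], [8.0, 4.0], [0.0, 4.0]]))
        shape = estimate_shape(quad)
        assert shape.height_px == pytest.approx(8)
        assert shape.width_px == pytest.approx(4)

    def test_collinear_contour_raises(self):
        line = Contour(np.column_stack([np.arange(6, dtype=float),
                                        np.arange(6, dtype=float)]))
        with pytest.raises(NoParticleError):
            estimate_shape(line)


class TestMeasurePixels:
    def test_bead_diameter_within_five_percent(self, render_bead_px):
        frame = render_bead_px(30.0, seed=1)
        shape = measure_pixels(frame.image_u8)
        assert 28.5 <= shape.height_px <= 31.5
        assert 28.5 <= shape.width_px <= 31.5

    def test_blank_frame_raises_no_particle(self):
        with pytest.raises(NoParticleError):
            measure_pixels(np.full((120, 120), 230, dtype=np.uint8))

    def test_noisy_ellipse_recovered_within_ten_percent(self):
        optics = OpticsSpec(noise_sigma=5 / 255, frame_side_px=120)
        spec = ParticleSpec("ellipse", 36 * 0.33, 24 * 0.33, angle_deg=20)
        frame = render_frame(spec, optics, seed=5)
        shape = measure_pixels(frame.image_u8)
        assert shape.height_px == pytest.approx(36, rel=0.10)
        assert shape.width_px == pytest.approx(24, rel=0.10)

    def test_translation_invariance_within_two_percent(self, render_bead_px):
        sizes = []
        for seed in range(6):  # jitter places the bead at 6 different positions
            frame = render_bead_px(30.0, seed=seed, noise_sigma=0.0, jitter=20.0)
            shape = measure_pixels(frame.image_u8)
            sizes.append(shape.height_px)
        assert (max(sizes) - min(sizes)) / max(sizes) <= 0.02

    def test_height_monotone_in_true_diameter(self, render_bead_px):
        means = []
        for d in (10, 20, 30, 40, 50, 60):
            vals = [measure_pixels(render_bead_px(d, seed=s).image_u8).height_px
                    for s in range(20)]
            means.append(np.mean(vals))
        assert np.all(np.diff(means) > 0)

    def test_circularity_of_beads(self, render_bead_px):
        for seed in range(5):
            shape = measure_pixels(render_bead_px(30.0, seed=seed).image_u8)
            assert abs(shape.height_px - shape.width_px) / shape.height_px <= 0.05

    def test_resized_frame_measurement_maps_to_original_pixels(self):
        # 256 px frame is resized to 120 internally; result must be ~30 px anyway
        optics = OpticsSpec(frame_side_px=256)
        frame = render_frame(ParticleSpec.circle(30 * 0.33), optics, seed=2)
        shape = measure_pixels(frame.image_u8)
        assert shape.height_px == pytest.approx(30, rel=0.12)
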