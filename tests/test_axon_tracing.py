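import numpy as np
import pytest
import scipy.ndimage as ndi

from axontracer import (
    DegenerateImageError,
    DetectionParams,
    EmptyRoiSignal,
    FixtureSpec,
    RoiMask,
    apply_roi_and_crop,
    binarize_response,
    cleanup_skeleton,
    detect_tissue_holes,
    extract_skeleton,
    fill_holes_with_mean,
    full_image_roi,
    generate_axon_image,
    invert_8bit,
    label_individual_axons,
    render_detail_overlay,
    render_overlay,
    ridge_response,
    trace_axons,
)

from _oracles import bfs_label


def roi_from(mask):
    return RoiMask(mask=mask, source_mode="entire_image")


class TestApplyRoiAndCrop:
    def test_crop_is_tight_bounding_box(self):
        plane = np.arange(1000 * 1000, dtype=np.int64).reshape(1000, 1000) % 251
        plane = plane.astype(np.uint8)
        mask = np.zeros((1000, 1000), dtype=bool)
        mask[100:200, 200:300] = True
        cropped, offset = apply_roi_and_crop(plane, roi_from(mask))
        assert cropped.shape == (100, 100)
        assert offset == (100, 200)
        np.testing.assert_array_equal(cropped, plane[100:200, 200:300])

    def test_full_roi_is_identity(self):
        plane = np.random.default_rng(0).integers(0, 256, (30, 40)).astype(np.uint8)
        cropped, offset = apply_roi_and_crop(plane, full_image_roi(plane.shape))
        assert offset == (0, 0)
        np.testing.assert_array_equal(cropped, plane)

    def test_pixels_outside_roi_zeroed(self):
        plane = np.full((20, 20), 99, dtype=np.uint8)
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True
        mask[7, 7] = False  # interior exclusion
        cropped, _ = apply_roi_and_crop(plane, roi_from(mask))
        assert cropped[2, 2] == 0  # (7,7) in source coords
        assert cropped[0, 0] == 99

    def test_empty_roi_signals(self):
        with pytest.raises(EmptyRoiSignal):
            apply_roi_and_crop(np.zeros((5, 5), np.uint8), roi_from(np.zeros((5, 5), bool)))


class TestTissueHoles:
    def test_zero_block_flagged_exactly(self):
        p = DetectionParams(hole_min_area_px=500, hole_intensity_max=5)
        plane = np.full((200, 200), 100, dtype=np.uint8)
        plane[60:110, 60:110] = 0  # 2500-px hole
        holes = detect_tissue_holes(plane, p)
        expected = np.zeros((200, 200), dtype=bool)
        expected[60:110, 60:110] = True
        np.testing.assert_array_equal(holes, expected)
        _, sizes = bfs_label(holes)
        assert sizes == [2500]

    def test_small_dark_region_below_area_floor_ignored(self):
        p = DetectionParams(hole_min_area_px=500)
        plane = np.full((100, 100), 100, dtype=np.uint8)
        plane[10:20, 10:20] = 0  # 100 px < floor
        assert not detect_tissue_holes(plane, p).any()

    def test_uniform_plane_has_no_holes(self):
        plane = np.full((50, 50), 100, dtype=np.uint8)
        assert not detect_tissue_holes(plane, DetectionParams()).any()

    def test_all_dark_plane_is_degenerate(self):
        with pytest.raises(DegenerateImageError):
            detect_tissue_holes(np.zeros((50, 50), dtype=np.uint8), DetectionParams())

    def test_fill_with_non_hole_mean(self):
        plane = np.full((40, 40), 100, dtype=np.uint8)
        holes = np.zeros((40, 40), dtype=bool)
        holes[5:15, 5:15] = True
        plane[holes] = 0
        filled = fill_holes_with_mean(plane, holes)
        assert (filled[holes] == 100).all()
        np.testing.assert_array_equal(filled[~holes], plane[~holes])

    def test_fill_rounds_half_up(self):
        # non-hole pixels average 99.5 -> fill value 100
        plane = np.zeros((2, 4), dtype=np.uint8)
        plane[0] = [99, 100, 99, 100]
        holes = np.zeros((2, 4), dtype=bool)
        holes[1] = True
        filled = fill_holes_with_mean(plane, holes)
        assert (filled[1] == 100).all()

    def test_empty_hole_mask_is_identity(self):
        plane = np.random.default_rng(1).integers(0, 256, (10, 10)).astype(np.uint8)
        np.testing.assert_array_equal(fill_holes_with_mean(plane, np.zeros((10, 10), bool)), plane)

    def test_all_holes_degenerate(self):
        with pytest.raises(DegenerateImageError):
            fill_holes_with_mean(np.zeros((5, 5), np.uint8), np.ones((5, 5), bool))


class TestRidgeResponse:
    def test_constant_plane_gives_zero_response(self):
        plane = np.full((30, 30), 77, dtype=np.uint8)
        assert not ridge_response(plane, "x", 1.0).any()
        assert not ridge_response(plane, "y", 1.0).any()

    def test_horizontal_line_peaks_in_y_not_x(self):
        plane = np.zeros((41, 120), dtype=np.uint8)
        plane[20, 10:110] = 255
        ry = ridge_response(plane, "y", 1.0)
        rx = ridge_response(plane, "x", 1.0)
        # y-response maximal on the line interior
        assert (ry[20, 30:90] > 0.99).all()
        # x-response carries no structure along the line interior: it sits at
        # the normalized zero level, same as far-away background, well below
        # the peak (which lives at the line ends)
        background_level = rx[5, 60]
        np.testing.assert_allclose(rx[20, 30:90], background_level, atol=1e-3)
        assert rx[20, 30:90].max() < 0.9

    def test_matches_sampled_derivative_of_gaussian_kernel(self):
        rng = np.random.default_rng(6)
        plane = rng.integers(0, 256, (40, 60)).astype(np.uint8)
        sigma = 1.5
        radius = int(4 * sigma + 0.5)
        x = np.arange(-radius, radius + 1, dtype=np.float64)
        phi = np.exp(-(x**2) / (2 * sigma**2))
        phi /= phi.sum()
        d2 = phi * (x**2 - sigma**2) / sigma**4  # sampled second derivative of a Gaussian
        smoothed = ndi.correlate1d(plane.astype(np.float64), phi, axis=0, mode="reflect")
        oracle = -ndi.correlate1d(smoothed, d2, axis=1, mode="reflect")
        oracle = (oracle - oracle.min()) / (oracle.max() - oracle.min())
        resp = ridge_response(plane, "x", sigma)
        np.testing.assert_allclose(resp, oracle, atol=1e-7)

    def test_invert_8bit_is_involution(self):
        plane = np.random.default_rng(2).integers(0, 256, (16, 16)).astype(np.uint8)
        np.testing.assert_array_equal(invert_8bit(invert_8bit(plane)), plane)


class TestBinarizeResponse:
    def test_sensitivity_one_selects_positive_response(self):
        resp = np.array([[0.0, 0.001, 0.5, 1.0]])
        np.testing.assert_array_equal(
            binarize_response(resp, 1.0), np.array([[False, True, True, True]])
        )

    def test_sensitivity_zero_selects_only_maximal_response(self):
        resp = np.array([[0.0, 0.3, 0.999, 1.0]])
        np.testing.assert_array_equal(
            binarize_response(resp, 0.0), np.array([[False, False, False, True]])
        )

    def test_midrange_threshold_arithmetic(self):
        resp = np.array([[0.2, 0.6, 0.9]])
        np.testing.assert_array_equal(
            binarize_response(resp, 0.5), np.array([[False, True, True]])
        )


class TestExtractSkeleton:
    def test_empty_inputs_empty_skeleton(self):
        empty = np.zeros((10, 10), dtype=bool)
        assert not extract_skeleton(empty, empty).any()

    def test_wide_bar_thins_to_unit_width_centerline(self):
        bar = np.zeros((20, 110), dtype=bool)
        bar[8:13, 5:105] = True  # 5 px wide, 100 px long
        skel = extract_skeleton(bar, np.zeros_like(bar))
        length = skel.sum()
        assert 96 <= length <= 100
        assert not (skel[:-1, :-1] & skel[1:, :-1] & skel[:-1, 1:] & skel[1:, 1:]).any()

    def test_filled_disk_collapses_to_near_point(self):
        yy, xx = np.mgrid[:50, :50]
        disk = (yy - 25) ** 2 + (xx - 25) ** 2 <= 20**2
        skel = extract_skeleton(disk, np.zeros_like(disk))
        assert skel.sum() < 10

    def test_union_of_axes(self):
        a = np.zeros((10, 10), dtype=bool)
        b = np.zeros((10, 10), dtype=bool)
        a[3, 2:8] = True
        b[2:8, 6] = True
        skel = extract_skeleton(a, b)
        # both the horizontal and the vertical stroke survive thinning
        assert skel[3, 3] or skel[3, 2]
        assert skel[6, 6] or skel[7, 6]


class TestCleanupSkeleton:
    @staticmethod
    def components_mask(sizes, shape=(64, 200)):
        mask = np.zeros(shape, dtype=bool)
        col = 2
        for size in sizes:
            mask[2, col : col + size] = True
            col += size + 3
        return mask

    def test_strictly_above_survives(self):
        mask = self.components_mask([5, 30, 100])
        kept = cleanup_skeleton(mask, 20)
        _, sizes = bfs_label(kept)
        assert sorted(sizes) == [30, 100]

    def test_component_exactly_at_cleanup_removed(self):
        mask = self.components_mask([30])
        assert not cleanup_skeleton(mask, 30).any()

    def test_cleanup_zero_keeps_everything(self):
        mask = self.components_mask([1, 2, 7])
        np.testing.assert_array_equal(cleanup_skeleton(mask, 0), mask)

    def test_matches_bfs_oracle_on_random_binaries(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            mask = rng.random((64, 64)) < 0.25
            cleanup = int(rng.integers(0, 12))
            labels, sizes = bfs_label(mask)
            expected = np.zeros_like(mask)
            for label, size in enumerate(sizes, start=1):
                if size > cleanup:
                    expected |= labels == label
            np.testing.assert_array_equal(cleanup_skeleton(mask, cleanup), expected)


class TestLabelIndividualAxons:
    def test_two_disjoint_curves(self):
        mask = np.zeros((30, 200), dtype=bool)
        mask[5, 10:130] = True  # 120 px
        mask[20, 10:90] = True  # 80 px
        records = label_individual_axons(mask)
        assert sorted(r.length_px for r in records) == [80, 120]
        assert sum(r.length_px for r in records) == mask.sum()
        assert len({r.color for r in records}) == 2

    def test_empty_skeleton_gives_no_records(self):
        assert label_individual_axons(np.zeros((5, 5), bool)) == []

    def test_single_component(self):
        mask = np.zeros((10, 50), dtype=bool)
        mask[4, 5:45] = True
        records = label_individual_axons(mask)
        assert len(records) == 1 and records[0].length_px == mask.sum()

    def test_deterministic_labeling(self):
        rng = np.random.default_rng(23)
        mask = rng.random((40, 40)) < 0.1
        assert label_individual_axons(mask) == label_individual_axons(mask)


class TestRenderOverlay:
    def test_empty_skeleton_returns_original(self):
        original = np.random.default_rng(3).integers(0, 256, (10, 10, 3)).astype(np.uint8)
        out = render_overlay(original, np.zeros((10, 10), bool))
        np.testing.assert_array_equal(out, original)

    def test_exactly_skeleton_pixels_recolored_yellow(self):
        original = np.zeros((20, 20, 3), dtype=np.uint8)
        skel = np.zeros((20, 20), dtype=bool)
        skel[4, 3:13] = True  # 10 px
        out = render_overlay(original, skel)
        changed = (out != original).any(axis=2)
        assert changed.sum() == 10
        assert (out[changed] == (255, 255, 0)).all()

    def test_detail_overlay_uses_distinct_component_colors(self):
        skel = np.zeros((30, 60), dtype=bool)
        skel[5, 5:25] = True
        skel[15, 5:25] = True
        skel[25, 5:25] = True
        records = label_individual_axons(skel)
        out = render_detail_overlay(np.zeros((30, 60), dtype=np.uint8), skel, records)
        colors = {tuple(out[r, c]) for r, c in np.argwhere(skel)}
        assert len(colors) == 3


class TestTraceAxons:
    def test_recovers_fixture_curve_lengths(self):
        spec = FixtureSpec(seed=5, n_axons=3, image_size=(200, 256))
        img, truth = generate_axon_image(spec)
        plane = img.pixels[:, :, 1]
        result = trace_axons(plane, full_image_roi(plane.shape), DetectionParams(), detail=True)
        assert abs(result.total_length_px - truth.total_length) / truth.total_length < 0.10
        assert len(result.axons) == 3
        assert sum(a.length_px for a in result.axons) == result.total_length_px

    def test_blank_plane_traces_nothing(self):
        plane = np.zeros((100, 100), dtype=np.uint8)
        result = trace_axons(plane, full_image_roi(plane.shape), DetectionParams())
        assert result.total_length_px == 0

    def test_empty_roi_reports_zero_length(self):
        plane = np.full((50, 50), 120, dtype=np.uint8)
        result = trace_axons(plane, roi_from(np.zeros((50, 50), bool)), DetectionParams())
        assert result.total_length_px == 0

    def test_hole_filling_suppresses_false_edges(self):
        spec = FixtureSpec(seed=8, n_axons=0, image_size=(300, 256),
                           hole_rects=((60, 60, 50, 50), (180, 120, 60, 40)))
        img, _ = generate_axon_image(spec)
        plane = img.pixels[:, :, 1]
        p = DetectionParams()
        with_fill = trace_axons(plane, full_image_roi(plane.shape), p)
        without_fill = trace_axons(plane, full_image_roi(plane.shape), p, fill_holes=False)
        assert with_fill.total_length_px == 0
        assert without_fill.total_length_px > 0

    def test_skeleton_contained_in_roi(self):
        spec = FixtureSpec(seed=9, n_axons=4, image_size=(300, 256))
        img, _ = generate_axon_image(spec)
        plane = img.pixels[:, :, 1]
        mask = np.zeros(plane.shape, dtype=bool)
        mask[60:240, 40:220] = True
        roi = roi_from(mask)
        result = trace_axons(plane, roi, DetectionParams())
        r0, c0 = result.crop_offset
        inflated = np.zeros(plane.shape, dtype=bool)
        inflated[r0 : r0 + result.skeleton.shape[0], c0 : c0 + result.skeleton.shape[1]] = (
            result.skeleton
        )
        assert not (inflated & ~mask).any()

    def test_length_monotone_in_sensitivity_and_cleanup(self):
        spec = FixtureSpec(seed=10, n_axons=3, image_size=(200, 256))
        img, _ = generate_axon_image(spec)
        plane = img.pixels[:, :, 1]
        roi = full_image_roi(plane.shape)
        by_sensitivity = [
            trace_axons(plane, roi, DetectionParams(sensitivity=s)).total_length_px
            for s in (0.1, 0.25, 0.35, 0.5)
        ]
        assert by_sensitivity == sorted(by_sensitivity)
        by_cleanup = [
            trace_axons(plane, roi, DetectionParams(cleanup_px=c)).total_length_px
            for c in (0, 15, 30, 120)
        ]
        assert by_cleanup == sorted(by_cleanup, reverse=True)

    def test_skeleton_is_thin(self):
        spec = FixtureSpec(seed=11, n_axons=5, image_size=(300, 256))
        img, _ = generate_axon_image(spec)
        plane = img.pixels[:, :, 1]
        skel = trace_axons(plane, full_image_roi(plane.shape), DetectionParams()).skeleton
        assert not (skel[:-1, :-1] & skel[1:, :-1] & skel[:-1, 1:] & skel[1:, 1:]).any()
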