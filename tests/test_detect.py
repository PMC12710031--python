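"""Chart detection, patch localization and color sampling."""

import numpy as np
import pytest

from aircolor.chart import CHART_HEIGHT, CHART_WIDTH
from aircolor.detect import (DetectionParams, detect_chart,
                             extract_patch_colors, locate_patches)
from aircolor.geometry import pixels_in_polygon, project_points
from aircolor.synth import render_scene, sample_scene_truth


def _identity_detection(chart, scale=40.0):
    """A synthetic successful detection with a known axis-aligned pose."""
    from aircolor.detect import ChartDetection

    H = np.diag([scale, scale, 1.0])
    corners = project_points(H, np.array(chart.corner_coords))
    return ChartDetection(success=True, homography=H, corners_image=corners,
                          n_keypoint_matches=99, inlier_ratio=1.0)


class TestDetectChart:
    def test_template_self_match_is_identity_equivalent(self, chart, template):
        det = detect_chart(template, template,
                           DetectionParams(refine=False))
        assert det.success
        h, w = template.shape[:2]
        expected = np.array([[0, 0], [w, 0], [w, h], [0, h]], dtype=float)
        assert np.abs(det.corners_image - expected).max() < 0.1

    def test_known_warp_recovered_within_2px(self, chart, template,
                                             layout_corners):
        truth = sample_scene_truth(5, chart, noise_sigma=1.0)
        frame = render_scene(truth, chart)
        det = detect_chart(frame, template)
        assert det.success
        true_corners = project_points(truth.homography, layout_corners)
        err = np.sqrt(np.mean(np.sum((det.corners_image - true_corners) ** 2,
                                     axis=1)))
        assert err <= 2.0

    def test_chart_free_frame_fails_without_exception(self, chart, template):
        truth = sample_scene_truth(91, chart, chart_present=False)
        frame = render_scene(truth, chart)
        det = detect_chart(frame, template)
        assert not det.success
        assert det.n_keypoint_matches < 12

    def test_translation_equivariance(self, chart, template):
        truth = sample_scene_truth(7, chart, noise_sigma=0.0)
        frame = render_scene(truth, chart)
        det1 = detect_chart(frame, template)
        det2 = detect_chart(np.roll(frame, (13, 21), axis=(0, 1)), template)
        assert det1.success and det2.success
        shift = np.array([21.0, 13.0])
        assert np.abs(det2.corners_image - det1.corners_image - shift).max() < 0.5

    def test_detection_suite_corner_accuracy_and_no_false_positives(
            self, chart, template, layout_corners):
        """Random poses (rotation to 180 deg, scale 0.5-2x): corner RMS <= 2 px;
        chart-free frames never detect."""
        rng = np.random.default_rng(2024)
        sq_errs = []
        n_fail = 0
        for k in range(50):
            scale = float(rng.uniform(0.5, 2.0))
            dims = (760, 1000) if scale > 1.4 else (540, 720)
            truth = sample_scene_truth(10_000 + k, chart, dims=dims,
                                       scale_range=(scale, scale),
                                       rotation_range=(-180.0, 180.0),
                                       noise_sigma=1.0)
            det = detect_chart(render_scene(truth, chart), template)
            if not det.success:
                n_fail += 1
                continue
            true_corners = project_points(truth.homography, layout_corners)
            sq_errs.append(np.mean(np.sum(
                (det.corners_image - true_corners) ** 2, axis=1)))
        assert n_fail == 0
        assert float(np.sqrt(np.mean(sq_errs))) <= 2.0
        for k in range(5):
            truth = sample_scene_truth(20_000 + k, chart, chart_present=False)
            assert not detect_chart(render_scene(truth, chart), template).success


class TestLocatePatches:
    def test_identity_full_fraction_equals_layout_cells(self, chart):
        det = _identity_detection(chart, scale=40.0)
        polys = locate_patches(det, chart, inner_area_fraction=1.0)
        for i, poly in enumerate(polys, start=1):
            np.testing.assert_allclose(poly,
                                       chart.patch_cell_polygon(i) * 40.0,
                                       atol=1e-9)

    def test_area_fraction_scales_side_by_sqrt(self, chart):
        det = _identity_detection(chart, scale=40.0)
        polys = locate_patches(det, chart, inner_area_fraction=0.8)
        side = polys[0][1, 0] - polys[0][0, 0]
        assert side == pytest.approx(40.0 * np.sqrt(0.8))

    def test_centers_match_direct_projection(self, chart, template):
        truth = sample_scene_truth(3, chart, noise_sigma=0.0)
        frame = render_scene(truth, chart)
        det = detect_chart(frame, template)
        polys = locate_patches(det, chart, 0.8)
        centers = np.array([p.mean(axis=0) for p in polys])
        expected = project_points(det.homography,
                                  np.array([p.layout_center
                                            for p in chart.patches]))
        assert np.abs(centers - expected).max() < 0.5

    def test_failed_detection_raises(self, chart):
        from aircolor.detect import ChartDetection

        failed = ChartDetection(success=False, homography=None,
                                corners_image=None, n_keypoint_matches=0,
                                inlier_ratio=0.0, message="no matches")
        with pytest.raises(ValueError, match="failed"):
            locate_patches(failed, chart)

    def test_out_of_bounds_polygons_name_patches(self, chart):
        det = _identity_detection(chart, scale=40.0)
        with pytest.raises(ValueError, match=r"\[1"):
            locate_patches(det, chart, 0.8, image_shape=(40, 40, 3))


class TestExtractPatchColors:
    def _polys(self, chart, scale=40.0, fraction=0.8):
        return locate_patches(_identity_detection(chart, scale), chart,
                              fraction)

    def test_uniform_patch_mean_is_exact(self, chart):
        img = np.full((220, 320, 3), (120, 60, 30), dtype=np.uint8)
        obs = extract_patch_colors(img, self._polys(chart))
        np.testing.assert_array_equal(obs.mean_rgb,
                                      np.tile([120.0, 60.0, 30.0], (24, 1)))
        assert np.all(obs.n_pixels > 0)

    def test_gradient_mean_matches_pixel_enumeration_oracle(self, chart):
        shapely = pytest.importorskip("shapely.geometry")
        rng = np.random.default_rng(0)
        img = np.linspace(0, 255, 220 * 320 * 3).reshape(220, 320, 3)
        img += rng.normal(0, 5, img.shape)
        img = np.clip(img, 0, 255)
        polys = self._polys(chart)
        obs = extract_patch_colors(img, polys)
        for i in (0, 11, 23):
            poly = shapely.Polygon(polys[i])
            vals = [img[r, c] for r in range(220) for c in range(320)
                    if poly.contains(shapely.Point(c + 0.5, r + 0.5))]
            np.testing.assert_allclose(obs.mean_rgb[i],
                                       np.mean(vals, axis=0), atol=1e-9)

    def test_border_contamination_outside_polygon_is_ignored(self, chart):
        img = np.full((220, 320, 3), 100.0)
        polys = self._polys(chart, fraction=0.8)
        obs1 = extract_patch_colors(img, polys)
        # contaminate a 2-px ring outside each sampling polygon
        dirty = img.copy()
        outer = locate_patches(_identity_detection(chart, 40.0), chart, 1.0)
        for inner_poly, outer_poly in zip(polys, outer):
            rr_o, cc_o = pixels_in_polygon(outer_poly, img.shape)
            rr_i, cc_i = pixels_in_polygon(inner_poly, img.shape)
            ring = set(zip(rr_o, cc_o)) - set(zip(rr_i, cc_i))
            for r, c in ring:
                dirty[r, c] = 255.0
        obs2 = extract_patch_colors(dirty, polys)
        np.testing.assert_array_equal(obs1.mean_rgb, obs2.mean_rgb)

    def test_invariant_to_vertex_ordering(self, chart):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 255, (220, 320, 3))
        polys = self._polys(chart)
        rolled = [np.roll(p, 2, axis=0) for p in polys]
        obs1 = extract_patch_colors(img, polys)
        obs2 = extract_patch_colors(img, rolled)
        np.testing.assert_array_equal(obs1.mean_rgb, obs2.mean_rgb)

    def test_empty_polygon_raises_with_patch_index(self, chart):
        img = np.zeros((220, 320, 3))
        polys = self._polys(chart)
        polys[4] = np.array([[500.0, 500.0], [501.0, 500.0],
                             [501.0, 501.0], [500.0, 501.0]])
        with pytest.raises(ValueError, match="patch 5"):
            extract_patch_colors(img, polys)
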