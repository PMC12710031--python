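"""Segmentation, overlap scoring, consistency and strategy comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aircolor.colorimetry import ciede2000, srgb_to_lab
from aircolor.detect import PatchObservationSet
from aircolor.evaluate import (camera_consistency_report,
                               compare_fixed_vs_inflight, delta_e_map,
                               maturity_regression, overlap_ratio,
                               plot_color_summary, segment_by_threshold)


def make_obs(rgb, image_id="t"):
    return PatchObservationSet(mean_rgb=np.asarray(rgb, dtype=float),
                               n_pixels=np.full(24, 100),
                               included=np.ones(24, dtype=bool),
                               image_id=image_id)


class TestDeltaEMap:
    def test_uniform_image_at_reference_is_zero(self):
        img = np.full((6, 8, 3), (87, 108, 67), dtype=np.uint8)
        ref = srgb_to_lab([87, 108, 67])
        assert np.max(delta_e_map(img, ref)) == pytest.approx(0.0, abs=1e-9)

    def test_two_color_image_matches_scalar_metric(self):
        img = np.zeros((4, 6, 3), dtype=np.uint8)
        img[:, :3] = (87, 108, 67)
        img[:, 3:] = (200, 60, 40)
        ref = srgb_to_lab([100, 100, 100])
        dmap = delta_e_map(img, ref)
        assert len(np.unique(np.round(dmap, 9))) == 2
        assert dmap[0, 0] == pytest.approx(
            ciede2000(srgb_to_lab([87, 108, 67]), ref))
        assert dmap[0, 5] == pytest.approx(
            ciede2000(srgb_to_lab([200, 60, 40]), ref))

    def test_translation_invariant(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 255, (10, 12, 3), dtype=np.uint8)
        ref = srgb_to_lab([50, 120, 80])
        np.testing.assert_allclose(
            delta_e_map(np.roll(img, 3, axis=1), ref),
            np.roll(delta_e_map(img, ref), 3, axis=1))


class TestSegmentation:
    def test_all_zero_map_selects_everything(self):
        res = segment_by_threshold(np.zeros((5, 5)), 10.0)
        assert res.n_selected == 25 and res.n_total == 25

    def test_threshold_is_strict(self):
        dmap = np.array([[5.0, 15.0], [10.0, 9.999]])
        res = segment_by_threshold(dmap, 10.0)
        np.testing.assert_array_equal(res.mask,
                                      [[True, False], [False, True]])

    def test_count_matches_enumeration_on_synthetic_leaf_scene(self, chart):
        from aircolor.synth import render_scene, sample_scene_truth

        truth = sample_scene_truth(6, chart, gain_range=(1, 1),
                                   offset_range=(0, 0), noise_sigma=0.0)
        frame = render_scene(truth, chart)
        ref = srgb_to_lab([72, 112, 52])
        dmap = delta_e_map(frame, ref)
        res = segment_by_threshold(dmap, 10.0)
        brute = sum(1 for r in range(frame.shape[0])
                    for c in range(frame.shape[1]) if dmap[r, c] < 10.0)
        assert res.n_selected == brute
        assert 0 < res.n_selected < res.n_total

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            segment_by_threshold(np.zeros((2, 2)), 0.0)


class TestOverlapRatio:
    def test_identical_masks_give_one(self):
        m = np.random.default_rng(0).random((10, 10)) > 0.5
        assert overlap_ratio(m, m) == 1.0

    def test_disjoint_masks_give_zero(self):
        t = np.zeros((4, 4), dtype=bool)
        t[:2] = True
        assert overlap_ratio(~t, t) == 0.0

    def test_partial_overlap_hand_count(self):
        truth = np.zeros((10, 10), dtype=bool)
        truth.ravel()[:100] = True  # all 100 pixels
        predicted = np.zeros((10, 10), dtype=bool)
        predicted.ravel()[:37] = True
        assert overlap_ratio(predicted, truth) == pytest.approx(0.37)

    def test_monotone_under_growing_prediction(self):
        rng = np.random.default_rng(3)
        truth = rng.random((12, 12)) > 0.4
        small = rng.random((12, 12)) > 0.7
        large = small | (rng.random((12, 12)) > 0.6)
        assert overlap_ratio(large, truth) >= overlap_ratio(small, truth)

    def test_empty_truth_raises(self):
        with pytest.raises(ValueError, match="empty"):
            overlap_ratio(np.ones((3, 3), dtype=bool),
                          np.zeros((3, 3), dtype=bool))


class TestCameraConsistency:
    def test_identical_perfect_cameras_give_all_zero(self, chart):
        obs = {f"cam{i}": make_obs(chart.reference_srgb_matrix)
               for i in range(3)}
        rep = camera_consistency_report(obs, chart)
        # packaged reference Lab is stored at 4 decimals, leaving ~4e-5 dE
        assert rep["mean_delta_e_original"] == pytest.approx(0.0, abs=1e-3)
        assert rep["mean_intracluster_original"] == pytest.approx(0.0, abs=1e-6)

    def test_distorted_cameras_get_tighter_after_correction(self, chart):
        rng = np.random.default_rng(14)
        obs = {}
        for i in range(4):
            gain = rng.uniform(0.55, 0.95, 3)
            offset = rng.uniform(-8, 8, 3)
            obs[f"cam{i}"] = make_obs(np.clip(
                chart.reference_srgb_matrix * gain + offset, 0, 255))
        rep = camera_consistency_report(obs, chart)
        assert rep["mean_intracluster_corrected"] < rep["mean_intracluster_original"]
        assert rep["mean_delta_e_corrected"] < rep["mean_delta_e_original"]
        # every synthetic distortion seed tightens, not just the average
        per_patch = rep["per_patch"]
        assert (per_patch.intracluster_corrected
                <= per_patch.intracluster_original + 1e-9).all()

    def test_two_cameras_match_hand_computed_cluster_distance(self, chart):
        a = chart.reference_srgb_matrix
        b = np.clip(a + 10.0, 0, 255)
        rep = camera_consistency_report(
            {"a": make_obs(a), "b": make_obs(b)}, chart)
        lab_a, lab_b = srgb_to_lab(a), srgb_to_lab(b)
        for i in (0, 11, 23):
            expected = np.linalg.norm(lab_a[i] - lab_b[i]) / 2.0
            got = rep["per_patch"].loc[i, "intracluster_original"]
            assert got == pytest.approx(expected, abs=1e-9)

    def test_single_camera_rejected(self, chart):
        with pytest.raises(ValueError, match="2 cameras"):
            camera_consistency_report(
                {"only": make_obs(chart.reference_srgb_matrix)}, chart)


class TestPlotColorSummary:
    def test_uniform_gray_gives_two_thirds(self):
        img = np.full((10, 10, 3), 100, dtype=np.uint8)
        s = plot_color_summary(img, np.ones((10, 10), dtype=bool))
        assert s.normalized_r_plus_b == pytest.approx(2 / 3)

    def test_pure_green_gives_zero(self):
        img = np.zeros((5, 5, 3), dtype=np.uint8)
        img[..., 1] = 200
        s = plot_color_summary(img, np.ones((5, 5), dtype=bool))
        assert s.normalized_r_plus_b == 0.0

    def test_two_tone_region_matches_bruteforce_mean(self):
        img = np.zeros((6, 6, 3), dtype=float)
        img[:3] = (40, 80, 20)
        img[3:] = (90, 50, 70)
        poly = np.array([[1.0, 1.0], [5.0, 1.0], [5.0, 5.0], [1.0, 5.0]])
        s = plot_color_summary(img, poly)
        from aircolor.geometry import pixels_in_polygon

        rr, cc = pixels_in_polygon(poly, img.shape)
        expected = np.mean([img[r, c] for r, c in zip(rr, cc)], axis=0)
        np.testing.assert_allclose(s.mean_rgb, expected, atol=1e-12)
        assert s.n_pixels == len(rr)

    @given(scale=st.floats(0.2, 2.0))
    @settings(derandomize=True, max_examples=30)
    def test_index_invariant_to_brightness_scaling(self, scale):
        img = np.zeros((4, 4, 3), dtype=float)
        img[:] = (60.0, 110.0, 35.0)
        mask = np.ones((4, 4), dtype=bool)
        base = plot_color_summary(img, mask).normalized_r_plus_b
        scaled = plot_color_summary(np.clip(img * scale, 0, 255),
                                    mask).normalized_r_plus_b
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_empty_region_raises(self):
        with pytest.raises(ValueError, match="no pixels"):
            plot_color_summary(np.zeros((4, 4, 3)),
                               np.zeros((4, 4), dtype=bool))


class TestMaturityRegression:
    def test_recovers_noiseless_linear_relation(self):
        x = np.linspace(0.3, 0.6, 10)
        y = 40.0 - 30.0 * x
        res = maturity_regression(x, y)
        assert res["slope"] == pytest.approx(-30.0)
        assert res["r_squared"] == pytest.approx(1.0)


class TestCompareFixedVsInflight:
    def _series_obs(self, chart, levels, gain=(0.9, 0.95, 0.85)):
        obs = []
        for i, level in enumerate(levels):
            rgb = np.clip(chart.reference_srgb_matrix * np.asarray(gain)
                          * level, 0, 255)
            obs.append(make_obs(rgb, image_id=f"f{i}"))
        return obs

    def test_constant_series_strategies_agree(self, chart):
        obs = self._series_obs(chart, [0.9] * 5)
        res = compare_fixed_vs_inflight(obs, chart, [0, 2, 4])
        s = res["summary"]
        for key in ("fixed_0", "fixed_2", "fixed_4"):
            assert abs(s[key] - s["inflight"]) <= 0.5

    def test_drifting_series_inflight_wins(self, chart):
        levels = np.linspace(1.0, 0.65, 7)
        obs = self._series_obs(chart, levels)
        res = compare_fixed_vs_inflight(obs, chart, [0, 3, 6])
        s = res["summary"]
        assert s["inflight"] <= s["fixed_0"]
        assert s["inflight"] <= s["fixed_3"]
        assert s["inflight"] <= s["fixed_6"]

    def test_mean_illumination_reference_is_best_fixed(self, chart):
        levels = np.linspace(1.0, 0.65, 7)  # frame 3 sits at the mean level
        obs = self._series_obs(chart, levels)
        res = compare_fixed_vs_inflight(obs, chart, [0, 3, 6])
        s = res["summary"]
        assert s["fixed_3"] < s["fixed_0"]
        assert s["fixed_3"] < s["fixed_6"]

    def test_bad_reference_index_rejected(self, chart):
        obs = self._series_obs(chart, [1.0, 0.9])
        with pytest.raises(ValueError, match="out of range"):
            compare_fixed_vs_inflight(obs, chart, [5])
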