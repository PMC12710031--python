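"""Downstream analyses: color-threshold segmentation, cross-sensor
consistency, plot color summaries, and the fixed-reference vs in-flight
correction comparison.

These are the analyses a phenotyping study runs once frames are
color-corrected: find canopy pixels whose color sits within a dE00
threshold of a ground-truth leaf color, score the agreement against
labeled leaf areas, summarize per-plot canopy color (including the
chlorophyll-sensitive normalized (R+B) index, (R+B)/(R+G+B) on plot-mean
channels), quantify how tightly different cameras agree in Lab space, and
compare per-frame correction against correcting a whole series with one
fixed reference frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chart import ReferenceChart
from .colorimetry import ciede2000, intracluster_distance, srgb_to_lab
from .correct import correct_observations, fit_ccm, mean_patch_delta_e
from .detect import PatchObservationSet
from .geometry import pixels_in_polygon

DEFAULT_SEGMENTATION_THRESHOLD = 10.0


@dataclass(frozen=True)
class SegmentationResult:
    """Pixels whose color error against a reference falls under a threshold."""

    mask: np.ndarray
    threshold: float
    reference_lab: tuple[float, float, float]
    n_selected: int
    n_total: int


@dataclass(frozen=True)
class PlotColorSummary:
    """Mean color of one field plot."""

    plot_id: str
    mean_rgb: tuple[float, float, float]
    mean_lab: tuple[float, float, float]
    normalized_r_plus_b: float
    n_pixels: int


def delta_e_map(image, reference_lab) -> np.ndarray:
    """Per-pixel CIEDE2000 against a single reference Lab color."""
    lab = srgb_to_lab(np.asarray(image, dtype=float)[..., :3])
    ref = np.asarray(reference_lab, dtype=float)
    return np.asarray(ciede2000(lab, ref))


def segment_by_threshold(delta_map, threshold: float = DEFAULT_SEGMENTATION_THRESHOLD,
                         reference_lab=(0.0, 0.0, 0.0)) -> SegmentationResult:
    """Select pixels with dE strictly below the threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    dm = np.asarray(delta_map, dtype=float)
    mask = dm < threshold
    return SegmentationResult(mask=mask, threshold=float(threshold),
                              reference_lab=tuple(np.asarray(reference_lab, dtype=float)),
                              n_selected=int(mask.sum()), n_total=int(mask.size))


def overlap_ratio(predicted, truth) -> float:
    """|predicted AND truth| / |truth|."""
    p = np.asarray(predicted, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    n_truth = int(t.sum())
    if n_truth == 0:
        raise ValueError("ground-truth region is empty")
    return float(np.logical_and(p, t).sum() / n_truth)


def camera_consistency_report(per_camera_observations: dict[str, PatchObservationSet],
                              chart: ReferenceChart) -> dict:
    """Cross-sensor color accuracy and consistency, before and after CCM.

    Each camera's chart observations are corrected with that camera's own
    fitted CCM. Returns per-camera mean patch dE00 (original/corrected),
    per-patch intracluster distances across cameras in Lab space
    (original/corrected), and grand means of both.
    """
    cameras = sorted(per_camera_observations)
    if len(cameras) < 2:
        raise ValueError("consistency analysis needs at least 2 cameras")
    ref_lab = chart.reference_lab_matrix

    lab_orig, lab_corr = {}, {}
    camera_rows = []
    for cam in cameras:
        obs = per_camera_observations[cam]
        ccm = fit_ccm(obs, chart)
        lab_orig[cam] = srgb_to_lab(np.clip(obs.mean_rgb, 0, 255))
        lab_corr[cam] = srgb_to_lab(correct_observations(obs, ccm))
        camera_rows.append({
            "camera": cam,
            "mean_delta_e_original": float(np.mean(ciede2000(lab_orig[cam], ref_lab))),
            "mean_delta_e_corrected": float(np.mean(ciede2000(lab_corr[cam], ref_lab))),
        })

    patch_rows = []
    for i in range(24):
        cluster_orig = np.array([lab_orig[cam][i] for cam in cameras])
        cluster_corr = np.array([lab_corr[cam][i] for cam in cameras])
        patch_rows.append({
            "patch": i + 1,
            "intracluster_original": intracluster_distance(cluster_orig),
            "intracluster_corrected": intracluster_distance(cluster_corr),
        })

    per_camera = pd.DataFrame(camera_rows)
    per_patch = pd.DataFrame(patch_rows)
    return {
        "per_camera": per_camera,
        "per_patch": per_patch,
        "mean_delta_e_original": float(per_camera["mean_delta_e_original"].mean()),
        "mean_delta_e_corrected": float(per_camera["mean_delta_e_corrected"].mean()),
        "mean_intracluster_original": float(per_patch["intracluster_original"].mean()),
        "mean_intracluster_corrected": float(per_patch["intracluster_corrected"].mean()),
    }


def plot_color_summary(image, plot_region, plot_id: str = "plot") -> PlotColorSummary:
    """Mean color of a plot region (pixel polygon or boolean mask)."""
    arr = np.asarray(image, dtype=float)
    region = np.asarray(plot_region)
    if region.ndim == 2 and region.shape[1] == 2:  # polygon vertices
        rr, cc = pixels_in_polygon(region, arr.shape)
    else:
        mask = region.astype(bool)
        if mask.shape != arr.shape[:2]:
            raise ValueError("mask shape does not match image")
        rr, cc = np.nonzero(mask)
    if rr.size == 0:
        raise ValueError(f"plot region {plot_id!r} covers no pixels")
    mean_rgb = arr[rr, cc, :3].mean(axis=0)
    r, g, b = mean_rgb
    total = r + g + b
    nrb = float((r + b) / total) if total > 0 else 0.0
    return PlotColorSummary(plot_id=plot_id,
                            mean_rgb=tuple(mean_rgb),
                            mean_lab=tuple(srgb_to_lab(np.clip(mean_rgb, 0, 255))),
                            normalized_r_plus_b=nrb,
                            n_pixels=int(rr.size))


def maturity_regression(color_values, maturity_days) -> dict:
    """OLS of maturity date on a color index; reports slope, R^2 and p."""
    from scipy.stats import linregress

    res = linregress(np.asarray(color_values, dtype=float),
                     np.asarray(maturity_days, dtype=float))
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r_squared": float(res.rvalue**2), "p_value": float(res.pvalue)}


def compare_fixed_vs_inflight(observations: list[PatchObservationSet],
                              chart: ReferenceChart,
                              reference_frame_indices: list[int]) -> dict:
    """Per-frame CCMs vs a single fixed-reference CCM for a whole series.

    ``observations`` holds the chart observations of every frame in
    acquisition order. For each fixed reference index, one CCM is fitted
    on that frame and applied to all frames; the in-flight strategy fits
    a fresh CCM per frame. Reports per-frame mean patch dE00 for every
    strategy plus summary means.
    """
    n = len(observations)
    if n < 2:
        raise ValueError("need at least 2 frames to compare strategies")
    for idx in reference_frame_indices:
        if not 0 <= idx < n:
            raise ValueError(f"reference frame index {idx} out of range 0..{n - 1}")

    strategies: dict[str, list[float]] = {}
    strategies["uncorrected"] = [mean_patch_delta_e(obs, chart)
                                 for obs in observations]
    inflight = []
    for obs in observations:
        ccm = fit_ccm(obs, chart)
        inflight.append(mean_patch_delta_e(obs, chart, ccm))
    strategies["inflight"] = inflight
    for idx in reference_frame_indices:
        fixed_ccm = fit_ccm(observations[idx], chart)
        strategies[f"fixed_{idx}"] = [mean_patch_delta_e(obs, chart, fixed_ccm)
                                      for obs in observations]

    per_frame = pd.DataFrame(strategies)
    per_frame.insert(0, "frame", np.arange(n))
    summary = {name: float(np.mean(vals)) for name, vals in strategies.items()}
    return {"per_frame": per_frame, "summary": summary}
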