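"""End-to-end batch pipeline: detect, correct, mask, and report per frame.

For every input frame the pipeline (1) locates the chart, (2) samples the
24 patch means, (3) drops overexposed patches, (4) fits the frame's own
CCM and corrects the frame, (5) writes the chart-occlusion mask, and (6)
records chart color error before and after correction. Frames where the
chart cannot be found are recorded as failures and the run continues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as aio
from .chart import ReferenceChart, load_reference_chart
from .correct import (DEFAULT_MIN_PATCHES, DEFAULT_OVEREXPOSURE_THRESHOLD,
                      apply_ccm, filter_overexposed, fit_ccm,
                      mean_patch_delta_e)
from .detect import DetectionParams, detect_chart, extract_patch_colors, locate_patches
from .mosaic import DEFAULT_LENGTH_EXPAND, DEFAULT_WIDTH_EXPAND, make_mask

logger = logging.getLogger("aircolor")

IMAGE_SUFFIXES = (".png", ".tif", ".tiff", ".jpg", ".jpeg")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    input_dir: str
    template_path: str
    output_dir: str
    chart_variant: str = "classic-srgb-d65"
    overexposure_threshold: float = DEFAULT_OVEREXPOSURE_THRESHOLD
    min_patches: int = DEFAULT_MIN_PATCHES
    inner_area_fraction: float = 0.8
    length_expand: float = DEFAULT_LENGTH_EXPAND
    width_expand: float = DEFAULT_WIDTH_EXPAND
    corrected_suffix: str = "_corrected"
    detection: DetectionParams = field(default_factory=DetectionParams)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        det = DetectionParams(**raw.pop("detection", {}))
        return cls(detection=det, **raw)


@dataclass
class RunReport:
    """Outcome of a pipeline run."""

    per_image: pd.DataFrame
    n_images: int
    n_failed: int

    @property
    def mean_delta_e_original(self) -> float:
        ok = self.per_image[self.per_image.success]
        return float(ok.delta_e_original.mean()) if len(ok) else float("nan")

    @property
    def mean_delta_e_corrected(self) -> float:
        ok = self.per_image[self.per_image.success]
        return float(ok.delta_e_corrected.mean()) if len(ok) else float("nan")


def process_frame(image, template, chart: ReferenceChart, config: RunConfig,
                  image_id: str):
    """Run detection through correction for one frame.

    Returns (record dict, artifacts dict); artifacts is None on failure.
    """
    detection = detect_chart(image, template, config.detection, image_id=image_id)
    if not detection.success:
        logger.warning("[%s] chart not found: %s", image_id, detection.message)
        return ({"image_id": image_id, "success": False,
                 "message": detection.message,
                 "n_patches_used": 0,
                 "delta_e_original": np.nan, "delta_e_corrected": np.nan},
                None)
    polygons = locate_patches(detection, chart, config.inner_area_fraction,
                              image_shape=np.asarray(image).shape)
    observations = extract_patch_colors(image, polygons, image_id=image_id)
    observations = filter_overexposed(observations, config.overexposure_threshold)
    n_excluded = int((~observations.included).sum())
    if n_excluded:
        logger.warning("[%s] %d overexposed patches excluded: %s", image_id,
                       n_excluded,
                       sorted(set(range(1, 25)) - set(observations.included_indices)))
    ccm = fit_ccm(observations, chart, min_patches=config.min_patches)
    corrected = apply_ccm(image, ccm)
    mask_spec, mask_raster = make_mask(detection, config.length_expand,
                                       config.width_expand,
                                       image_shape=np.asarray(image).shape)
    record = {
        "image_id": image_id,
        "success": True,
        "message": "ok",
        "n_patches_used": len(ccm.patches_used),
        "delta_e_original": mean_patch_delta_e(observations, chart),
        "delta_e_corrected": mean_patch_delta_e(observations, chart, ccm),
    }
    artifacts = {"detection": detection, "observations": observations,
                 "ccm": ccm, "corrected": corrected,
                 "mask_spec": mask_spec, "mask": mask_raster}
    return record, artifacts


def run_pipeline(config: RunConfig) -> RunReport:
    """Process every image in the input directory and write artifacts.

    Per image: detection JSON, CCM JSON, corrected PNG, mask PNG; run
    level: a CSV report of per-frame chart color error before and after
    correction.
    """
    input_dir = Path(config.input_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = sorted(p for p in input_dir.iterdir()
                   if p.suffix.lower() in IMAGE_SUFFIXES)
    if not paths:
        raise ValueError(f"no input images found in {input_dir}")
    template = aio.read_image(config.template_path)
    chart = load_reference_chart(config.chart_variant)

    records = []
    for path in paths:
        image_id = path.stem
        try:
            image = aio.read_image(path)
        except Exception as exc:  # unreadable frame: record and continue
            logger.warning("[%s] unreadable image: %s", image_id, exc)
            records.append({"image_id": image_id, "success": False,
                            "message": f"unreadable: {exc}", "n_patches_used": 0,
                            "delta_e_original": np.nan,
                            "delta_e_corrected": np.nan})
            continue
        record, artifacts = process_frame(image, template, chart, config, image_id)
        records.append(record)
        if artifacts is None:
            continue
        aio.write_json(out_dir / f"{image_id}_detection.json",
                       artifacts["detection"].to_dict())
        aio.write_json(out_dir / f"{image_id}_ccm.json", artifacts["ccm"].to_dict())
        aio.write_image(out_dir / f"{image_id}{config.corrected_suffix}.png",
                        artifacts["corrected"])
        aio.write_image(out_dir / f"{image_id}_mask.png", artifacts["mask"])

    report = pd.DataFrame(records)
    report.to_csv(out_dir / "run_report.csv", index=False)
    manifest = report[["image_id"]].copy()
    manifest["mask"] = manifest.image_id + "_mask.png"
    manifest.to_csv(out_dir / "mask_manifest.csv", index=False)
    n_failed = int((~report.success).sum())
    return RunReport(per_image=report, n_images=len(report), n_failed=n_failed)
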