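"""Raster and metadata I/O: images, exposure settings, JSON artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from PIL import Image

from .colorimetry import ExposureSettings

# EXIF tag ids for exposure metadata.
_EXIF_EXPOSURE_TIME = 0x829A
_EXIF_F_NUMBER = 0x829D
_EXIF_ISO = 0x8827


def read_image(path) -> np.ndarray:
    """Read an RGB raster (PNG/TIFF/JPEG) as uint8 (h, w, 3)."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return np.ascontiguousarray(arr[..., :3])


def write_image(path, image) -> None:
    iio.imwrite(path, np.asarray(image))


def read_exposure_from_exif(path) -> ExposureSettings | None:
    """Exposure settings from EXIF, or None when the tags are absent."""
    with Image.open(path) as img:
        exif = img.getexif()
        merged = dict(exif)
        try:
            merged.update(exif.get_ifd(0x8769))  # EXIF sub-IFD
        except KeyError:
            pass
    iso = merged.get(_EXIF_ISO)
    shutter = merged.get(_EXIF_EXPOSURE_TIME)
    aperture = merged.get(_EXIF_F_NUMBER)
    if iso is None or shutter is None or aperture is None:
        return None
    if isinstance(iso, (tuple, list)):
        iso = iso[0]
    return ExposureSettings(iso=float(iso), shutter_s=float(shutter),
                            aperture_n=float(aperture))


def read_exposure_sidecar(path) -> dict[str, ExposureSettings]:
    """Sidecar CSV with columns image_id, iso, shutter_s, aperture_n."""
    df = pd.read_csv(path)
    required = {"image_id", "iso", "shutter_s", "aperture_n"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sidecar table missing columns: {sorted(missing)}")
    return {str(row.image_id): ExposureSettings(iso=float(row.iso),
                                                shutter_s=float(row.shutter_s),
                                                aperture_n=float(row.aperture_n))
            for row in df.itertuples()}


def write_json(path, payload: dict) -> None:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")
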