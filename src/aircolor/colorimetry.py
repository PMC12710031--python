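"""Color-space conversion and the color metrics used throughout the pipeline.

All colorimetry is fixed to the sRGB / D65 / 2-degree-observer convention:
8-bit sRGB values are decoded with the standard transfer function, taken to
XYZ under the D65 white point and then to CIELAB. Color differences are
reported as CIEDE2000 (dE00) with the standard parametric factors
kL = kC = kH = 1; values near 1 are at the threshold of human perception
and ~4-5 is the commonly cited practical acceptability limit.

Brightness comparisons across frames use the mean RGB of the chart's 18 %
gray patch, normalized to reference exposure settings (ISO 100, 1/100 s,
f/8) so that camera auto-exposure does not masquerade as illumination
change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2lab

GRAY_PATCH_INDEX = 22  # the 18 % gray patch of the 24-patch chart

__all__ = [
    "ExposureSettings",
    "REFERENCE_EXPOSURE",
    "GRAY_PATCH_INDEX",
    "srgb_to_lab",
    "ciede2000",
    "normalize_brightness",
    "brightness_of_gray_patch",
    "intracluster_distance",
]


@dataclass(frozen=True)
class ExposureSettings:
    """Camera exposure settings of one frame.

    Parameters
    ----------
    iso : float
        ISO sensitivity (e.g. 100).
    shutter_s : float
        Exposure time in seconds (a shutter speed of 1/100 s is 0.01).
    aperture_n : float
        Aperture f-number (f/8 is 8.0).
    """

    iso: float
    shutter_s: float
    aperture_n: float

    def __post_init__(self) -> None:
        for field in ("iso", "shutter_s", "aperture_n"):
            value = getattr(self, field)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"{field} must be strictly positive, got {value!r}")


#: Standard conditions that per-frame brightness is normalized to.
REFERENCE_EXPOSURE = ExposureSettings(iso=100.0, shutter_s=1.0 / 100.0, aperture_n=8.0)


def srgb_to_lab(rgb) -> np.ndarray:
    """Convert 8-bit-scale sRGB values to CIELAB (D65, 2 degrees).

    Parameters
    ----------
    rgb : array-like, shape (..., 3)
        sRGB values on the 0-255 scale (floats allowed).

    Returns
    -------
    ndarray, shape (..., 3)
        L* in [0, 100] with a*, b* unbounded.
    """
    arr = np.asarray(rgb, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError(f"expected trailing axis of size 3, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite RGB input")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError(
            f"RGB values must lie in [0, 255]; got range [{arr.min()}, {arr.max()}]"
        )
    return rgb2lab(arr / 255.0)


def ciede2000(lab_x, lab_y) -> np.ndarray | float:
    """CIEDE2000 color difference between Lab triples (kL = kC = kH = 1).

    Both inputs are broadcast against each other over leading axes; the
    trailing axis holds (L*, a*, b*). Returns a scalar for a single pair.
    """
    x = np.asarray(lab_x, dtype=float)
    y = np.asarray(lab_y, dtype=float)
    if x.shape[-1] != 3 or y.shape[-1] != 3:
        raise ValueError("Lab inputs need a trailing axis of size 3")
    L1, a1, b1 = np.moveaxis(x, -1, 0)
    L2, a2, b2 = np.moveaxis(y, -1, 0)

    C1 = np.hypot(a1, b1)
    C2 = np.hypot(a2, b2)
    C_bar = (C1 + C2) / 2.0
    G = 0.5 * (1.0 - np.sqrt(C_bar**7 / (C_bar**7 + 25.0**7)))
    ap1 = (1.0 + G) * a1
    ap2 = (1.0 + G) * a2
    Cp1 = np.hypot(ap1, b1)
    Cp2 = np.hypot(ap2, b2)

    hp1 = np.degrees(np.arctan2(b1, ap1)) % 360.0
    hp2 = np.degrees(np.arctan2(b2, ap2)) % 360.0
    hp1 = np.where((ap1 == 0) & (b1 == 0), 0.0, hp1)
    hp2 = np.where((ap2 == 0) & (b2 == 0), 0.0, hp2)

    dLp = L2 - L1
    dCp = Cp2 - Cp1

    dhp = hp2 - hp1
    dhp = np.where(dhp > 180.0, dhp - 360.0, dhp)
    dhp = np.where(dhp < -180.0, dhp + 360.0, dhp)
    dhp = np.where((Cp1 * Cp2) == 0, 0.0, dhp)
    dHp = 2.0 * np.sqrt(Cp1 * Cp2) * np.sin(np.radians(dhp) / 2.0)

    Lp_bar = (L1 + L2) / 2.0
    Cp_bar = (Cp1 + Cp2) / 2.0

    hsum = hp1 + hp2
    habs = np.abs(hp1 - hp2)
    hp_bar = np.where(habs <= 180.0, hsum / 2.0,
                      np.where(hsum < 360.0, (hsum + 360.0) / 2.0, (hsum - 360.0) / 2.0))
    hp_bar = np.where((Cp1 * Cp2) == 0, hsum, hp_bar)

    T = (1.0
         - 0.17 * np.cos(np.radians(hp_bar - 30.0))
         + 0.24 * np.cos(np.radians(2.0 * hp_bar))
         + 0.32 * np.cos(np.radians(3.0 * hp_bar + 6.0))
         - 0.20 * np.cos(np.radians(4.0 * hp_bar - 63.0)))

    d_theta = 30.0 * np.exp(-(((hp_bar - 275.0) / 25.0) ** 2))
    R_C = 2.0 * np.sqrt(Cp_bar**7 / (Cp_bar**7 + 25.0**7))
    S_L = 1.0 + 0.015 * (Lp_bar - 50.0) ** 2 / np.sqrt(20.0 + (Lp_bar - 50.0) ** 2)
    S_C = 1.0 + 0.045 * Cp_bar
    S_H = 1.0 + 0.015 * Cp_bar * T
    R_T = -np.sin(np.radians(2.0 * d_theta)) * R_C

    dE = np.sqrt((dLp / S_L) ** 2
                 + (dCp / S_C) ** 2
                 + (dHp / S_H) ** 2
                 + R_T * (dCp / S_C) * (dHp / S_H))
    if dE.ndim == 0:
        return float(dE)
    return dE


def load_ciede2000_reference_pairs() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The published CIEDE2000 worked-example dataset (34 Lab pairs).

    Returns (lab_x, lab_y, expected_delta_e); the expected values are the
    published four-decimal results and exercise every discontinuity of
    the formula (hue wraparound, gray axis, the rotation term).
    """
    from importlib import resources

    text = resources.files("aircolor.data").joinpath(
        "ciede2000_reference_pairs.csv").read_text()
    data = np.loadtxt(text.splitlines()[1:], delimiter=",")
    return data[:, 0:3], data[:, 3:6], data[:, 6]


def normalize_brightness(l_raw: float, raw: ExposureSettings,
                         ref: ExposureSettings = REFERENCE_EXPOSURE) -> float:
    """Normalize a brightness reading to reference exposure settings.

    l_std = l_raw * (ISO_ref / ISO_raw) * (t_ref / t_raw) * (N_raw / N_ref)^2

    The aperture ratio enters squared with the raw f-number in the
    numerator; see the methods note for a discussion of this convention.
    """
    if not isinstance(raw, ExposureSettings):
        raw = ExposureSettings(*raw)
    if not isinstance(ref, ExposureSettings):
        ref = ExposureSettings(*ref)
    return float(l_raw
                 * (ref.iso / raw.iso)
                 * (ref.shutter_s / raw.shutter_s)
                 * (raw.aperture_n / ref.aperture_n) ** 2)


def brightness_of_gray_patch(observations) -> float:
    """Mean of the R, G and B channel means of the 18 % gray patch (patch 22).

    Raises if patch 22 is flagged as excluded (e.g. overexposed) in the
    observation set.
    """
    idx = GRAY_PATCH_INDEX
    if not observations.included[idx - 1]:
        raise ValueError(
            f"gray patch {idx} is excluded from {observations.image_id!r} "
            "(overexposed or not observed); brightness undefined"
        )
    return float(np.mean(observations.mean_rgb[idx - 1]))


def intracluster_distance(cluster) -> float:
    """Mean Euclidean distance of Lab points from their centroid.

    One patch observed by several cameras forms a cluster in Lab space;
    a smaller value means better cross-sensor agreement.
    """
    pts = np.asarray(cluster, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected an (n, 3) array of Lab points, got {pts.shape}")
    if pts.shape[0] < 2:
        raise ValueError("intracluster distance needs at least 2 points")
    centroid = pts.mean(axis=0)
    return float(np.mean(np.linalg.norm(pts - centroid, axis=1)))
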