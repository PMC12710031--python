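"""Fitting and applying the bias-augmented color correction matrix (CCM).

The correction is the linear model C = [A | 1] M, where A holds the
observed patch RGB means (n x 3, 0-255 scale), the appended column of ones
absorbs per-channel offsets, C holds the chart's reference sRGB values and
M is the 4 x 3 correction matrix. M is the least-squares minimizer of
||[A|1] M - C||_F, solved by QR-based least squares rather than the
normal-equations inverse for numerical stability — the two agree whenever
the augmented matrix has full column rank. The fitted M is then applied to
every pixel of the frame and the result clipped back to [0, 255].

Patches whose observed mean exceeds 250 on any channel are excluded from
the fit beforehand: auto-exposure over bright field scenes routinely
saturates the most reflective patches, and saturated values carry no
usable photometric information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .chart import ReferenceChart
from .colorimetry import ciede2000, srgb_to_lab
from .detect import PatchObservationSet

DEFAULT_OVEREXPOSURE_THRESHOLD = 250.0
DEFAULT_MIN_PATCHES = 6
RECOMMENDED_MIN_PATCHES = 9

__all__ = [
    "CorrectionMatrix",
    "filter_overexposed",
    "fit_ccm",
    "apply_ccm",
    "correct_observations",
    "patch_count_sensitivity",
    "DEFAULT_OVEREXPOSURE_THRESHOLD",
    "DEFAULT_MIN_PATCHES",
]


@dataclass(frozen=True)
class CorrectionMatrix:
    """A fitted 4 x 3 color correction matrix with provenance.

    Rows of ``M`` correspond to (R, G, B, bias); columns to corrected
    (R, G, B). ``patches_used`` lists the 1-based patch indices that
    entered the fit.
    """

    M: np.ndarray
    patches_used: tuple[int, ...]
    source_image_id: str | None = None
    fit_residual_rms: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "M", np.asarray(self.M, dtype=float))
        if self.M.shape != (4, 3):
            raise ValueError(f"M must be 4x3, got {self.M.shape}")
        if not np.all(np.isfinite(self.M)):
            raise ValueError("M contains non-finite entries")

    @classmethod
    def identity(cls) -> "CorrectionMatrix":
        return cls(M=np.vstack([np.eye(3), np.zeros(3)]),
                   patches_used=tuple(range(1, 25)))

    def to_dict(self) -> dict:
        return {
            "M": [[round(float(v), 10) for v in row] for row in self.M],
            "patches_used": [int(i) for i in self.patches_used],
            "source_image_id": self.source_image_id,
            "fit_residual_rms": round(float(self.fit_residual_rms), 8),
        }


def filter_overexposed(observations: PatchObservationSet,
                       threshold: float = DEFAULT_OVEREXPOSURE_THRESHOLD
                       ) -> PatchObservationSet:
    """Flag patches with any channel mean strictly above ``threshold``.

    Filtering only clears the ``included`` flag; means are preserved so
    that excluded patches can still be inspected or evaluated.
    """
    if not 0.0 < threshold <= 255.0:
        raise ValueError(f"threshold must be in (0, 255], got {threshold}")
    over = np.any(observations.mean_rgb > threshold, axis=1)
    return observations.with_included(observations.included & ~over)


def fit_ccm(observations: PatchObservationSet, chart: ReferenceChart,
            min_patches: int = DEFAULT_MIN_PATCHES) -> CorrectionMatrix:
    """Least-squares fit of the CCM over the included patches."""
    mask = observations.included
    n = int(mask.sum())
    if n < min_patches:
        raise ValueError(f"only {n} included patches; at least {min_patches} "
                         "required to fit a CCM")
    if n < RECOMMENDED_MIN_PATCHES:
        warnings.warn(
            f"fitting a CCM on {n} patches; correction accuracy is known to "
            f"stabilize only from about {RECOMMENDED_MIN_PATCHES} patches",
            stacklevel=2)
    A = observations.mean_rgb[mask]
    C = chart.reference_srgb_matrix[mask]
    aug = np.hstack([A, np.ones((n, 1))])
    if np.linalg.matrix_rank(aug) < 4:
        raise ValueError(
            "augmented observation matrix is rank-deficient; the included "
            "patches are collinear in RGB — include more (or less collinear) "
            "patches")
    M, *_ = np.linalg.lstsq(aug, C, rcond=None)
    residual = aug @ M - C
    rms = float(np.sqrt(np.mean(residual**2)))
    return CorrectionMatrix(M=M, patches_used=tuple(int(i) for i in
                                                    observations.included_indices),
                            source_image_id=observations.image_id,
                            fit_residual_rms=rms)


def apply_ccm(image, ccm: CorrectionMatrix):
    """Correct every pixel of an RGB frame with the fitted matrix.

    The frame must be on the 0-255 scale used for the fit; float frames on
    a 0-1 scale are rejected rather than silently miscorrected. Output is
    clipped to [0, 255] and returned in the input dtype.
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an (h, w, 3) RGB frame")
    if np.issubdtype(arr.dtype, np.floating) and np.nanmax(arr) <= 1.0 and np.nanmax(arr) > 0:
        raise ValueError("frame appears to be on a 0-1 float scale; the CCM "
                         "is fitted on the 0-255 scale")
    flat = arr.reshape(-1, 3).astype(float)
    corrected = np.hstack([flat, np.ones((flat.shape[0], 1))]) @ ccm.M
    corrected = np.clip(corrected, 0.0, 255.0).reshape(arr.shape)
    if np.issubdtype(arr.dtype, np.integer):
        return np.rint(corrected).astype(arr.dtype)
    return corrected


def correct_observations(observations: PatchObservationSet,
                         ccm: CorrectionMatrix) -> np.ndarray:
    """Apply the CCM to the 24 patch means; returns a clipped (24, 3) array."""
    aug = np.hstack([observations.mean_rgb, np.ones((24, 1))])
    return np.clip(aug @ ccm.M, 0.0, 255.0)


def mean_patch_delta_e(observations: PatchObservationSet, chart: ReferenceChart,
                       ccm: CorrectionMatrix | None = None,
                       patch_mask=None) -> float:
    """Mean CIEDE2000 of (optionally corrected) patch means vs reference."""
    rgb = observations.mean_rgb if ccm is None else correct_observations(observations, ccm)
    lab = srgb_to_lab(np.clip(rgb, 0, 255))
    de = ciede2000(lab, chart.reference_lab_matrix)
    if patch_mask is not None:
        de = de[np.asarray(patch_mask, dtype=bool)]
    return float(np.mean(de))


def _select_patches(candidates: np.ndarray, n: int, policy: str,
                    chart: ReferenceChart, rng: np.random.Generator) -> np.ndarray:
    if policy == "random":
        return rng.choice(candidates, size=n, replace=False)
    if policy == "saturation-descending":
        ref = chart.reference_srgb_matrix[candidates - 1]
        saturation = ref.max(axis=1) - ref.min(axis=1)
        order = candidates[np.argsort(-saturation, kind="stable")]
        return order[:n]
    raise ValueError(f"unknown selection policy {policy!r}")


def patch_count_sensitivity(observations: PatchObservationSet,
                            chart: ReferenceChart, counts,
                            selection_order: str = "random",
                            replicates: int = 20, seed: int = 0,
                            min_patches: int = DEFAULT_MIN_PATCHES):
    """Correction accuracy as a function of the number of patches fitted.

    For each count n, fits a CCM on n of the included patches (chosen by
    the selection policy, re-seeded per replicate for the random policy),
    corrects all 24 observed patch means and reports the mean CIEDE2000
    against the reference Lab values. Returns a pandas DataFrame with
    columns ``n_patches`` and ``mean_delta_e``.
    """
    import pandas as pd

    candidates = observations.included_indices
    rows = []
    for n in counts:
        if n < min_patches or n > candidates.size:
            warnings.warn(f"skipping n={n}: outside solvable range "
                          f"[{min_patches}, {candidates.size}]", stacklevel=2)
            continue
        n_rep = replicates if selection_order == "random" and n < candidates.size else 1
        values = []
        for rep in range(n_rep):
            rng = np.random.default_rng((seed, n, rep))
            chosen = _select_patches(candidates, n, selection_order, chart, rng)
            sub_mask = np.zeros(24, dtype=bool)
            sub_mask[np.asarray(chosen) - 1] = True
            sub = observations.with_included(sub_mask)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    ccm = fit_ccm(sub, chart, min_patches=min_patches)
            except ValueError:
                continue
            values.append(mean_patch_delta_e(observations, chart, ccm))
        if values:
            rows.append({"n_patches": int(n),
                         "mean_delta_e": float(np.mean(values))})
    return pd.DataFrame(rows)
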