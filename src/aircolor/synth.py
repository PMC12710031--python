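"""Ground-truthed synthetic aerial frames for end-to-end verification.

A synthetic frame emulates what the imaging platform sees: a flat field
background sprinkled with leaf-like elliptical regions, and the reference
chart rendered at a known pose (a homography from chart layout space into
image pixels, roughly 180 x 270 px at the default geometry, with uniform
in-plane rotation and mild perspective jitter). Radiometric distortion is
a per-channel affine model on the 0-255 scale,

    frame = clip(gain * (illumination * ideal) + offset + noise),

with multiplicative per-channel gains standing in for sensor response and
color cast, a scalar illumination multiplier for ambient light, additive
offsets, and clipped Gaussian pixel noise. Every frame carries its
:class:`SceneTruth` so downstream estimates can be checked against the
exact generating parameters.

The random color cast draws each channel gain uniformly from [0.5, 1.0] —
attenuation only, so the cast itself can never push patches into
overexposure. Flight series repeat the same scene layout over a sequence
of frames while the illumination multiplier follows a constant, linearly
drifting, or stochastic-walk profile, mimicking changing ambient light
during a mission.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import ellipse
from skimage.transform import ProjectiveTransform

from .chart import (CHART_HEIGHT, CHART_MARGIN, CHART_WIDTH, N_COLS, N_ROWS,
                    PATCH_GAP, PATCH_SIDE, ReferenceChart)
from .colorimetry import (REFERENCE_EXPOSURE, ExposureSettings, ciede2000,
                          srgb_to_lab)
from .geometry import polygon_is_convex, project_points

DEFAULT_DIMS = (540, 720)           # (height, width) of a synthetic frame
DEFAULT_CHART_LONG_PX = 270.0       # long-axis chart size, emulating ~180x270 px
CHART_FRAME_RGB = (35.0, 35.0, 35.0)
FIELD_BASE_RGB = (151.0, 131.0, 101.0)
LEAF_BASE_RGB = (72.0, 112.0, 52.0)


@dataclass(frozen=True)
class LeafSpec:
    center: tuple[float, float]     # (row, col)
    radii: tuple[float, float]
    angle_deg: float
    rgb: tuple[float, float, float]


@dataclass(frozen=True)
class BackgroundSpec:
    base_rgb: tuple[float, float, float] = FIELD_BASE_RGB
    leaves: tuple[LeafSpec, ...] = ()


@dataclass(frozen=True)
class SceneTruth:
    """Exact generating parameters of one synthetic frame."""

    seed: int
    homography: np.ndarray | None   # layout -> image; None = no chart in frame
    gain: tuple[float, float, float] = (1.0, 1.0, 1.0)
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    illumination: float = 1.0
    exposure: ExposureSettings = REFERENCE_EXPOSURE
    background: BackgroundSpec = field(default_factory=BackgroundSpec)
    noise_sigma: float = 1.0
    dims: tuple[int, int] = DEFAULT_DIMS

    def __post_init__(self) -> None:
        if any(g <= 0 for g in self.gain):
            raise ValueError("gains must be strictly positive")
        if self.illumination <= 0:
            raise ValueError("illumination multiplier must be strictly positive")

    def distorted_patch_rgb(self, chart: ReferenceChart) -> np.ndarray:
        """Patch means the distortion model implies, before noise (24 x 3)."""
        ideal = chart.reference_srgb_matrix
        out = (np.asarray(self.gain) * (self.illumination * ideal)
               + np.asarray(self.offset))
        return np.clip(out, 0.0, 255.0)

    def to_dict(self) -> dict:
        return {
            "seed": int(self.seed),
            "homography": None if self.homography is None
            else [[round(float(v), 10) for v in row] for row in self.homography],
            "gain": [round(float(g), 8) for g in self.gain],
            "offset": [round(float(o), 8) for o in self.offset],
            "illumination": round(float(self.illumination), 8),
            "exposure": {"iso": self.exposure.iso,
                         "shutter_s": self.exposure.shutter_s,
                         "aperture_n": self.exposure.aperture_n},
            "noise_sigma": float(self.noise_sigma),
            "dims": list(self.dims),
        }


def _chart_color_lut(chart: ReferenceChart) -> np.ndarray:
    lut = np.zeros((N_ROWS * N_COLS, 3))
    for p in chart.patches:
        lut[p.index - 1] = p.reference_srgb
    return lut


def _paint_chart(ideal: np.ndarray, homography: np.ndarray,
                 chart: ReferenceChart) -> None:
    """Render the chart into ``ideal`` (float RGB, modified in place)."""
    corners = project_points(homography, np.array(chart.corner_coords))
    h, w = ideal.shape[:2]
    x0 = max(int(np.floor(corners[:, 0].min())) - 1, 0)
    x1 = min(int(np.ceil(corners[:, 0].max())) + 1, w)
    y0 = max(int(np.floor(corners[:, 1].min())) - 1, 0)
    y1 = min(int(np.ceil(corners[:, 1].max())) + 1, h)
    if x1 <= x0 or y1 <= y0:
        return
    cols, rows = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
    centers = np.column_stack([cols.ravel() + 0.5, rows.ravel() + 0.5])
    layout = project_points(np.linalg.inv(homography), centers)
    u, v = layout[:, 0], layout[:, 1]

    on_chart = (u >= 0) & (u < CHART_WIDTH) & (v >= 0) & (v < CHART_HEIGHT)
    pitch = PATCH_SIDE + PATCH_GAP
    pu, pv = u - CHART_MARGIN, v - CHART_MARGIN
    col = np.floor(pu / pitch).astype(int)
    row = np.floor(pv / pitch).astype(int)
    in_cell = ((pu >= 0) & (pv >= 0)
               & (col >= 0) & (col < N_COLS) & (row >= 0) & (row < N_ROWS)
               & (pu - col * pitch < PATCH_SIDE) & (pv - row * pitch < PATCH_SIDE))
    colors = np.empty((centers.shape[0], 3))
    colors[:] = CHART_FRAME_RGB
    lut = _chart_color_lut(chart)
    idx = np.clip(row * N_COLS + col, 0, 23)
    colors[in_cell] = lut[idx[in_cell]]

    rr = rows.ravel()[on_chart]
    cc = cols.ravel()[on_chart]
    ideal[rr, cc] = colors[on_chart]


def render_ideal_scene(truth: SceneTruth, chart: ReferenceChart) -> np.ndarray:
    """The undistorted float scene: background, leaves, chart."""
    h, w = truth.dims
    ideal = np.empty((h, w, 3))
    ideal[:] = truth.background.base_rgb
    for leaf in truth.background.leaves:
        rr, cc = ellipse(leaf.center[0], leaf.center[1], leaf.radii[0],
                         leaf.radii[1], shape=(h, w),
                         rotation=np.deg2rad(leaf.angle_deg))
        ideal[rr, cc] = leaf.rgb
    if truth.homography is not None:
        corners = project_points(truth.homography, np.array(chart.corner_coords))
        if (corners[:, 0].min() < 0 or corners[:, 0].max() > w
                or corners[:, 1].min() < 0 or corners[:, 1].max() > h):
            raise ValueError("chart pose places the chart outside the frame")
        _paint_chart(ideal, truth.homography, chart)
    return ideal


def render_scene(truth: SceneTruth, chart: ReferenceChart) -> np.ndarray:
    """Render the distorted 8-bit frame for a scene truth (deterministic)."""
    ideal = render_ideal_scene(truth, chart)
    out = (np.asarray(truth.gain) * (truth.illumination * ideal)
           + np.asarray(truth.offset))
    if truth.noise_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence((int(truth.seed), 777)))
        out = out + rng.normal(0.0, truth.noise_sigma, out.shape)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def render_chart_template(chart: ReferenceChart,
                          long_axis_px: float = 405.0) -> np.ndarray:
    """Render an ideal face-on chart crop for use as the detection template.

    The template spans the full chart (margin included), matching the
    assumption the detector makes when composing homographies. The default
    resolution is 1.5x the in-frame chart size: a finer template carries
    more keypoints, which matters for frames with strong casts, while SIFT
    scale invariance keeps matching unaffected.
    """
    scale = long_axis_px / CHART_WIDTH
    w = int(np.ceil(CHART_WIDTH * scale))
    h = int(np.ceil(CHART_HEIGHT * scale))
    homography = np.diag([scale, scale, 1.0])
    truth = SceneTruth(seed=0, homography=homography, noise_sigma=0.0,
                       dims=(h, w),
                       background=BackgroundSpec(base_rgb=CHART_FRAME_RGB))
    return render_scene(truth, chart)


def sample_background(rng: np.random.Generator, dims,
                      n_leaves: int = 25) -> BackgroundSpec:
    """Random leaf-like ellipses over the field base color."""
    h, w = dims
    leaves = []
    base = np.asarray(LEAF_BASE_RGB)
    for _ in range(n_leaves):
        rgb = np.clip(base + rng.uniform(-25, 25, 3), 0, 255)
        leaves.append(LeafSpec(
            center=(float(rng.uniform(0, h)), float(rng.uniform(0, w))),
            radii=(float(rng.uniform(8, 26)), float(rng.uniform(4, 14))),
            angle_deg=float(rng.uniform(0, 180)),
            rgb=tuple(rgb)))
    return BackgroundSpec(leaves=tuple(leaves))


def sample_chart_homography(rng: np.random.Generator, dims,
                            chart_long_px: float = DEFAULT_CHART_LONG_PX,
                            scale_range: tuple[float, float] = (1.0, 1.0),
                            rotation_range: tuple[float, float] = (0.0, 360.0),
                            perspective_jitter: float = 0.03,
                            center=None) -> np.ndarray:
    """Random chart pose: scaled, rotated, mildly perspective-distorted.

    ``perspective_jitter`` jitters each projected corner by up to that
    fraction of the chart size, emulating near-nadir but not perfectly
    fronto-parallel geometry.
    """
    h, w = dims
    scale_px = (chart_long_px / CHART_WIDTH) * rng.uniform(*scale_range)
    theta = np.deg2rad(rng.uniform(*rotation_range))
    half_diag = 0.5 * scale_px * np.hypot(CHART_WIDTH, CHART_HEIGHT)
    margin = half_diag * (1.0 + 3.0 * perspective_jitter) + 3.0
    if 2 * margin >= min(h, w):
        raise ValueError(f"frame {dims} too small for chart of scale {scale_px:.1f}")
    if center is None:
        center = (rng.uniform(margin, w - margin), rng.uniform(margin, h - margin))
    layout_corners = np.array([[0.0, 0.0], [CHART_WIDTH, 0.0],
                               [CHART_WIDTH, CHART_HEIGHT], [0.0, CHART_HEIGHT]])
    centered = layout_corners - [CHART_WIDTH / 2, CHART_HEIGHT / 2]
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    ideal_corners = (centered * scale_px) @ rot.T + center
    for _ in range(100):
        jitter = rng.uniform(-perspective_jitter, perspective_jitter,
                             (4, 2)) * scale_px * CHART_HEIGHT
        corners = ideal_corners + jitter
        if polygon_is_convex(corners):
            break
    else:  # pragma: no cover - jitter small enough that this never triggers
        corners = ideal_corners
    tform = ProjectiveTransform.from_estimate(layout_corners, corners)
    if not tform:
        raise RuntimeError("failed to build chart pose homography")
    return tform.params / tform.params[2, 2]


def sample_scene_truth(seed: int, chart: ReferenceChart,
                       dims=DEFAULT_DIMS,
                       gain_range: tuple[float, float] = (0.5, 1.0),
                       offset_range: tuple[float, float] = (-10.0, 10.0),
                       illumination: float = 1.0,
                       noise_sigma: float = 1.0,
                       scale_range: tuple[float, float] = (1.0, 1.0),
                       rotation_range: tuple[float, float] = (0.0, 360.0),
                       chart_present: bool = True,
                       exposure: ExposureSettings = REFERENCE_EXPOSURE) -> SceneTruth:
    """Draw a random distorted scene truth (deterministic in ``seed``)."""
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 101)))
    background = sample_background(rng, dims)
    homography = None
    if chart_present:
        homography = sample_chart_homography(rng, dims,
                                             scale_range=scale_range,
                                             rotation_range=rotation_range)
    gain = tuple(rng.uniform(*gain_range, 3))
    offset = tuple(rng.uniform(*offset_range, 3))
    return SceneTruth(seed=int(seed), homography=homography, gain=gain,
                      offset=offset, illumination=illumination,
                      exposure=exposure, background=background,
                      noise_sigma=noise_sigma, dims=tuple(dims))


def apply_color_cast(image, seed: int | None = None,
                     rng: np.random.Generator | None = None,
                     gains=None) -> tuple[np.ndarray, np.ndarray]:
    """Attenuate each channel by a random gain in [0.5, 1.0].

    Returns the cast frame and the applied gains (the ground truth).
    Gains may be forced for testing.
    """
    if gains is None:
        if rng is None:
            rng = np.random.default_rng(seed)
        gains = rng.uniform(0.5, 1.0, 3)
    gains = np.asarray(gains, dtype=float)
    arr = np.asarray(image)
    out = np.clip(arr.astype(float) * gains, 0, 255)
    if np.issubdtype(arr.dtype, np.integer):
        out = np.rint(out).astype(arr.dtype)
    return out, gains


def make_distortion_benchmark(n_frames: int, seed: int,
                              chart: ReferenceChart, dims=DEFAULT_DIMS,
                              noise_sigma: float = 1.0,
                              min_uncorrected_delta_e: float = 5.0
                              ) -> list[tuple[np.ndarray, SceneTruth]]:
    """Seeded benchmark of distorted frames with guaranteed-large casts.

    Gains are drawn in [0.5, 1.0] and offsets in [-10, 10]; draws whose
    implied uncorrected mean patch dE00 falls below
    ``min_uncorrected_delta_e`` are rejected and redrawn, so every
    benchmark frame is meaningfully distorted.
    """
    ref_lab = chart.reference_lab_matrix
    frames = []
    for i in range(n_frames):
        for attempt in range(200):
            truth = sample_scene_truth(seed * 100_003 + i * 97 + attempt,
                                       chart, dims=dims,
                                       noise_sigma=noise_sigma)
            distorted_lab = srgb_to_lab(truth.distorted_patch_rgb(chart))
            if float(np.mean(ciede2000(distorted_lab, ref_lab))) >= min_uncorrected_delta_e:
                break
        frames.append((render_scene(truth, chart), truth))
    return frames


@dataclass(frozen=True)
class FlightSeriesSpec:
    """A simulated mission: per-frame illumination and a fixed sensor."""

    n_frames: int
    dims: tuple[int, int] = DEFAULT_DIMS
    profile: str = "constant"           # constant | linear | walk
    illumination_start: float = 1.0
    illumination_end: float = 1.0
    walk_sigma: float = 0.05
    gain: tuple[float, float, float] = (1.0, 1.0, 1.0)
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sigma: float = 1.0
    seed: int = 0
    exposures: tuple[ExposureSettings, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.profile not in ("constant", "linear", "walk"):
            raise ValueError(f"unknown illumination profile {self.profile!r}")


def illumination_profile(spec: FlightSeriesSpec) -> np.ndarray:
    """Per-frame illumination multipliers for a series spec."""
    if spec.profile == "constant":
        levels = np.full(spec.n_frames, spec.illumination_start)
    elif spec.profile == "linear":
        levels = np.linspace(spec.illumination_start, spec.illumination_end,
                             spec.n_frames)
    else:  # stochastic multiplicative walk
        rng = np.random.default_rng(np.random.SeedSequence((int(spec.seed), 211)))
        steps = rng.normal(0.0, spec.walk_sigma, spec.n_frames - 1)
        levels = spec.illumination_start * np.exp(np.concatenate([[0.0],
                                                                  np.cumsum(steps)]))
        levels = np.clip(levels, 0.25, 1.6)
    if np.any(levels <= 0):
        raise ValueError("illumination profile produced non-positive levels")
    return levels


def generate_flight_series(spec: FlightSeriesSpec, chart: ReferenceChart
                           ) -> list[tuple[np.ndarray, SceneTruth]]:
    """Render one frame per mission step, chart present in every frame.

    The background layout is shared across the series (one field), the
    chart pose is re-sampled per frame with modest rotation, and the
    illumination multiplier follows the series profile.
    """
    levels = illumination_profile(spec)
    shared_rng = np.random.default_rng(np.random.SeedSequence((int(spec.seed), 303)))
    background = sample_background(shared_rng, spec.dims)
    series = []
    for i, level in enumerate(levels):
        pose_rng = np.random.default_rng(
            np.random.SeedSequence((int(spec.seed), 404, i)))
        homography = sample_chart_homography(pose_rng, spec.dims,
                                             rotation_range=(-25.0, 25.0))
        exposure = (spec.exposures[i] if spec.exposures is not None
                    else REFERENCE_EXPOSURE)
        truth = SceneTruth(seed=int(spec.seed) * 10_007 + i,
                           homography=homography, gain=spec.gain,
                           offset=spec.offset, illumination=float(level),
                           exposure=exposure, background=background,
                           noise_sigma=spec.noise_sigma, dims=spec.dims)
        series.append((render_scene(truth, chart), truth))
    return series
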