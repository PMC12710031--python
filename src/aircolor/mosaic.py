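"""Chart-occlusion masks and flight-overlap arithmetic for mosaicking input.

The chart (and the carrier platform around it) must be blanked out before
frames are handed to mosaicking software, otherwise the chart is blended
into the orthomosaic. The mask is the detected chart quadrilateral grown
symmetrically about its center — by 30 % per direction along the chart's
long axis and 50 % per direction along its short axis by default, sized to
cover the carrier's arms and rotors. Expansion is applied in the chart's
own axes (in layout space, through the homography), so rotated charts are
masked correctly.

Whether the blanked region can be filled from neighbouring frames is a
simple overlap question: with f forward overlap the next frame shares
round(height * f) pixel rows, and likewise for the side direction, which
must comfortably exceed the mask extents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chart import CHART_HEIGHT, CHART_WIDTH
from .detect import ChartDetection
from .geometry import (polygon_raster, project_points,
                       scale_polygon_about_center)

DEFAULT_LENGTH_EXPAND = 0.3
DEFAULT_WIDTH_EXPAND = 0.5

_LAYOUT_CORNERS = np.array([[0.0, 0.0], [CHART_WIDTH, 0.0],
                            [CHART_WIDTH, CHART_HEIGHT], [0.0, CHART_HEIGHT]])


@dataclass(frozen=True)
class MaskSpec:
    """Geometry of one chart-occlusion mask."""

    corners_image: np.ndarray       # detected chart quadrilateral (4 x 2, xy)
    length_expand: float
    width_expand: float
    expanded_polygon: np.ndarray    # grown quadrilateral (4 x 2, xy)
    image_shape: tuple[int, int]


def make_mask(detection: ChartDetection,
              length_expand: float = DEFAULT_LENGTH_EXPAND,
              width_expand: float = DEFAULT_WIDTH_EXPAND,
              image_shape=None) -> tuple[MaskSpec, np.ndarray]:
    """Build the occlusion mask for a detected chart.

    The long (6-column) axis is scaled by (1 + 2 * length_expand) and the
    short axis by (1 + 2 * width_expand) about the chart center, in layout
    space. Returns the mask geometry plus a binary uint8 raster (255 =
    masked) clipped to the image bounds.
    """
    if not detection.success:
        raise ValueError("cannot build a mask from a failed detection "
                         f"({detection.message})")
    if length_expand < 0 or width_expand < 0:
        raise ValueError("expansion fractions must be non-negative")
    if image_shape is None:
        raise ValueError("image_shape is required to rasterize the mask")
    expanded_layout = scale_polygon_about_center(
        _LAYOUT_CORNERS, 1.0 + 2.0 * length_expand, 1.0 + 2.0 * width_expand)
    expanded = project_points(detection.homography, expanded_layout)
    raster = polygon_raster(expanded, image_shape)
    spec = MaskSpec(corners_image=np.asarray(detection.corners_image, dtype=float),
                    length_expand=float(length_expand),
                    width_expand=float(width_expand),
                    expanded_polygon=expanded,
                    image_shape=tuple(image_shape[:2]))
    return spec, raster


@dataclass(frozen=True)
class OverlapResult:
    """Shared pixels between consecutive/adjacent frames, and sufficiency."""

    forward_px: int
    side_px: int
    sufficient: bool | None  # None when no mask extents were supplied


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def overlap_pixels(image_dims, forward_overlap: float, side_overlap: float,
                   mask_extents=None) -> OverlapResult:
    """Overlap in pixels implied by the flight plan.

    Parameters
    ----------
    image_dims : (width, height)
        Frame size in pixels.
    forward_overlap, side_overlap : float
        Overlap fractions in [0, 1). Forward overlap acts along the image
        height (flight direction), side overlap along the width.
    mask_extents : optional pair of mask extents in pixels
        When given, ``sufficient`` reports whether both overlaps strictly
        exceed the largest mask extent, i.e. whether masked content is
        always recoverable from a neighbouring frame.
    """
    width, height = image_dims
    for name, frac in (("forward_overlap", forward_overlap),
                       ("side_overlap", side_overlap)):
        if not 0.0 <= frac < 1.0:
            raise ValueError(f"{name} must be in [0, 1), got {frac}")
    forward_px = _round_half_up(height * forward_overlap)
    side_px = _round_half_up(width * side_overlap)
    sufficient = None
    if mask_extents is not None:
        largest = float(np.max(mask_extents))
        sufficient = bool(forward_px > largest and side_px > largest)
    return OverlapResult(forward_px=forward_px, side_px=side_px,
                         sufficient=sufficient)
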