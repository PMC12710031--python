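"""The 24-patch reference chart: layout geometry and reference colors.

The chart is a 4 x 6 grid of colored patches numbered 1..24 in row-major
order: row 1 holds natural colors (dark skin, light skin, ...), rows 2-3
saturated primaries, and row 4 the six neutral patches from white (19)
down to black (24); patch 22 is the 18 % gray patch used as the brightness
reference.

Layout space is chart-relative: the unit of length is one patch side,
origin at the top-left of the chart (outer edge of the margin), x running
rightward along the 6-column axis and y downward. All homographies in this
package map layout space to image pixel space.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

# Layout constants (units of one patch side).
PATCH_SIDE = 1.0
PATCH_GAP = 0.15
CHART_MARGIN = 0.25
N_ROWS, N_COLS = 4, 6
CHART_WIDTH = 2 * CHART_MARGIN + N_COLS * PATCH_SIDE + (N_COLS - 1) * PATCH_GAP
CHART_HEIGHT = 2 * CHART_MARGIN + N_ROWS * PATCH_SIDE + (N_ROWS - 1) * PATCH_GAP

_VARIANT_FILES = {
    "classic-srgb-d65": "colorchecker_classic_srgb_d65.csv",
}


@dataclass(frozen=True)
class PatchSpec:
    """One chart patch: identity, reference colors and layout position."""

    index: int
    name: str
    reference_srgb: tuple[float, float, float]
    reference_lab: tuple[float, float, float]
    grid_row: int
    grid_col: int
    layout_center: tuple[float, float]


@dataclass(frozen=True)
class ReferenceChart:
    """The full 24-patch chart with layout geometry and reference values."""

    variant: str
    patches: tuple[PatchSpec, ...]
    physical_width: float = CHART_WIDTH
    physical_height: float = CHART_HEIGHT
    grid: tuple[int, int] = (N_ROWS, N_COLS)
    corner_coords: tuple[tuple[float, float], ...] = field(
        default=((0.0, 0.0), (CHART_WIDTH, 0.0),
                 (CHART_WIDTH, CHART_HEIGHT), (0.0, CHART_HEIGHT)))

    def __post_init__(self) -> None:
        if len(self.patches) != 24:
            raise ValueError(f"chart must have 24 patches, got {len(self.patches)}")
        if [p.index for p in self.patches] != list(range(1, 25)):
            raise ValueError("patches must be ordered 1..24")

    @property
    def reference_srgb_matrix(self) -> np.ndarray:
        """24 x 3 matrix of reference sRGB values (0-255), row i = patch i+1."""
        return np.array([p.reference_srgb for p in self.patches], dtype=float)

    @property
    def reference_lab_matrix(self) -> np.ndarray:
        """24 x 3 matrix of reference Lab values under D65."""
        return np.array([p.reference_lab for p in self.patches], dtype=float)

    def patch(self, index: int) -> PatchSpec:
        if not 1 <= index <= 24:
            raise IndexError(f"patch index must be 1..24, got {index}")
        return self.patches[index - 1]

    def patch_cell_polygon(self, index: int, inner_area_fraction: float = 1.0) -> np.ndarray:
        """Corners (4 x 2, layout space) of a patch square, optionally shrunk.

        ``inner_area_fraction`` scales the square about its center so that
        the polygon covers that fraction of the patch area, i.e. the side
        scales by sqrt(fraction).
        """
        if not 0.0 < inner_area_fraction <= 1.0:
            raise ValueError("inner_area_fraction must be in (0, 1]")
        cx, cy = self.patch(index).layout_center
        half = 0.5 * PATCH_SIDE * float(np.sqrt(inner_area_fraction))
        return np.array([[cx - half, cy - half], [cx + half, cy - half],
                         [cx + half, cy + half], [cx - half, cy + half]])


def patch_layout_center(row: int, col: int) -> tuple[float, float]:
    """Layout-space center of the patch at 1-based (row, col)."""
    x = CHART_MARGIN + (col - 1) * (PATCH_SIDE + PATCH_GAP) + 0.5 * PATCH_SIDE
    y = CHART_MARGIN + (row - 1) * (PATCH_SIDE + PATCH_GAP) + 0.5 * PATCH_SIDE
    return (x, y)


def available_variants() -> tuple[str, ...]:
    return tuple(sorted(_VARIANT_FILES))


def load_reference_chart(variant: str = "classic-srgb-d65") -> ReferenceChart:
    """Load a packaged chart definition.

    Parameters
    ----------
    variant : str
        Chart variant id. ``"classic-srgb-d65"`` ships the widely published
        sRGB coordinates of the pre-2014 Classic chart edition, with Lab
        values under D65/2 degrees.
    """
    try:
        filename = _VARIANT_FILES[variant]
    except KeyError:
        raise ValueError(
            f"unknown chart variant {variant!r}; available: {available_variants()}"
        ) from None
    text = resources.files("aircolor.data").joinpath(filename).read_text()
    patches = []
    for rec in csv.DictReader(text.splitlines()):
        row, col = int(rec["row"]), int(rec["col"])
        patches.append(PatchSpec(
            index=int(rec["index"]),
            name=rec["name"],
            reference_srgb=(float(rec["R"]), float(rec["G"]), float(rec["B"])),
            reference_lab=(float(rec["L"]), float(rec["a"]), float(rec["b"])),
            grid_row=row,
            grid_col=col,
            layout_center=patch_layout_center(row, col),
        ))
    patches.sort(key=lambda p: p.index)
    return ReferenceChart(variant=variant, patches=tuple(patches))
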