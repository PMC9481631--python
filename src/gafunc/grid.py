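"""Fovea-centred standard grids and ETDRS subfield geometry.

En-face maps from different eyes are only comparable after two
normalizations: translation so the manually annotated foveal centre sits
exactly at the grid centre, and horizontal mirroring of left (OS) eyes so
that the +x direction is nasal for every eye. :func:`standardize` performs
both with bilinear resampling.

The ETDRS macular grid partitions the central 6-mm circle into nine
subfields: a 1-mm-diameter foveal disc, four parafoveal (inner ring,
0.5–1.5 mm radius) and four perifoveal (outer ring, 1.5–3 mm radius)
quadrants split along the 45° diagonals into superior, nasal, inferior and
temporal sectors. :func:`etdrs_labels` assigns every grid cell to one
subfield (or background) from its cell-centre polar coordinates.

Standard-grid coordinates: +x nasal, +y superior, origin at the fovea;
row 0 is the superior edge. Radius bins and sector angles are half-open,
so every cell receives exactly one label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .enface import EnFaceMap, Feature, Laterality

#: ETDRS ring radii in mm: foveal disc, inner ring, outer ring.
ETDRS_RADII_MM: Tuple[float, float, float] = (0.5, 1.5, 3.0)

OUTSIDE = 0
FOVEAL = 1
INNER_SUPERIOR, INNER_NASAL, INNER_INFERIOR, INNER_TEMPORAL = 2, 3, 4, 5
OUTER_SUPERIOR, OUTER_NASAL, OUTER_INFERIOR, OUTER_TEMPORAL = 6, 7, 8, 9

REGION_NAMES: Dict[int, str] = {
    FOVEAL: "foveal",
    INNER_SUPERIOR: "inner_superior",
    INNER_NASAL: "inner_nasal",
    INNER_INFERIOR: "inner_inferior",
    INNER_TEMPORAL: "inner_temporal",
    OUTER_SUPERIOR: "outer_superior",
    OUTER_NASAL: "outer_nasal",
    OUTER_INFERIOR: "outer_inferior",
    OUTER_TEMPORAL: "outer_temporal",
}

#: The nine subfield labels in table order.
REGION_LABELS: Tuple[int, ...] = tuple(REGION_NAMES)

INNER_REGIONS: Tuple[int, ...] = (2, 3, 4, 5)
OUTER_REGIONS: Tuple[int, ...] = (6, 7, 8, 9)


@dataclass
class StandardGrid:
    """Fovea-centred, laterality-normalized resampling of an en-face map.

    ``grid[i, j]`` covers the cell centred at
    ``x = (j + 0.5) * cell - extent`` (nasal positive) and
    ``y = extent - (i + 0.5) * cell`` (superior positive), where
    ``cell = 2 * extent / C``. The fovea sits at (0, 0), i.e. the centre
    cell for odd grid sizes. Cells that fall outside the scanned field
    carry ``fill_value``.
    """

    grid: np.ndarray
    extent_mm: float = 3.0
    feature: Optional[Feature] = None
    fill_value: float = 0.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2-D")
        if self.extent_mm <= 0:
            raise ValueError("extent_mm must be positive")
        if self.feature is not None:
            self.feature = Feature(self.feature)

    @property
    def cell_mm(self) -> Tuple[float, float]:
        r, c = self.grid.shape
        return (2.0 * self.extent_mm / r, 2.0 * self.extent_mm / c)

    @property
    def cell_area_mm2(self) -> float:
        dy, dx = self.cell_mm
        return float(dy * dx)


@dataclass
class EtdrsLabels:
    """Per-cell assignment of standard-grid cells to ETDRS subfields."""

    labels: np.ndarray
    extent_mm: float
    radii_mm: Tuple[float, float, float] = ETDRS_RADII_MM

    @property
    def cell_area_mm2(self) -> float:
        r, c = self.labels.shape
        return float((2.0 * self.extent_mm / r) * (2.0 * self.extent_mm / c))


def cell_centers(
    resolution: Tuple[int, int], extent_mm: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Cell-centre coordinate arrays ``(X, Y)`` in mm, fovea at (0, 0).

    ``X`` increases nasally with column index; ``Y`` decreases with row
    index so that row 0 is superior.
    """
    rows, cols = resolution
    x = (np.arange(cols) + 0.5) * (2.0 * extent_mm / cols) - extent_mm
    y = extent_mm - (np.arange(rows) + 0.5) * (2.0 * extent_mm / rows)
    return np.meshgrid(x, y)


def standardize(
    emap: EnFaceMap,
    resolution: Tuple[int, int] = (49, 49),
    extent_mm: float = 3.0,
    fill_value: float = 0.0,
) -> StandardGrid:
    """Resample an en-face map onto the fovea-centred standard grid.

    Left (OS) maps are mirrored horizontally first, so +x is nasal for
    every eye; the map is then bilinearly interpolated at the standard
    lattice of cell centres. Target cells whose source location lies
    outside the scanned field receive ``fill_value``.
    """
    if emap.fovea_xy_mm is None:
        raise ValueError("en-face map lacks a foveal annotation")
    if emap.laterality is None:
        raise ValueError("en-face map lacks laterality")
    src = emap.grid
    fx, fy = emap.fovea_xy_mm
    h_mm, w_mm = emap.field_mm
    if not (0.0 <= fx <= w_mm and 0.0 <= fy <= h_mm):
        raise ValueError("foveal annotation lies outside the scanned field")
    if Laterality(emap.laterality) == Laterality.OS:
        src = src[:, ::-1]
        fx = w_mm - fx

    X, Y = cell_centers(resolution, extent_mm)
    xs = fx + X  # source mm coordinates of the target cell centres
    ys = fy - Y  # source y runs downward from the superior edge
    row_f = ys / emap.spacing_mm[0] - 0.5
    col_f = xs / emap.spacing_mm[1] - 0.5
    # 'nearest' extends edge values into the outer half-cell band; cells
    # beyond the scanned field proper are overwritten with fill_value below
    out = map_coordinates(src, [row_f, col_f], order=1, mode="nearest")
    outside = (xs < 0.0) | (xs > w_mm) | (ys < 0.0) | (ys > h_mm)
    out[outside] = fill_value
    return StandardGrid(
        grid=out, extent_mm=extent_mm, feature=emap.feature, fill_value=fill_value
    )


def etdrs_labels(
    resolution: Tuple[int, int] = (49, 49),
    extent_mm: float = 3.0,
    radii_mm: Tuple[float, float, float] = ETDRS_RADII_MM,
) -> EtdrsLabels:
    """Label every standard-grid cell with its ETDRS subfield.

    Cell centres with radius < 0.5 mm are foveal; [0.5, 1.5) inner ring;
    [1.5, 3.0) outer ring; beyond 3 mm background (label 0). Sectors are
    split at the 45° diagonals: angles [45°, 135°) are superior,
    [135°, 225°) temporal (since +x is nasal), [225°, 315°) inferior, and
    the remaining horizontal sector nasal. All bins are half-open, so the
    assignment is a partition.
    """
    if extent_mm < radii_mm[-1]:
        raise ValueError("grid extent must cover the outer ETDRS ring")
    X, Y = cell_centers(resolution, extent_mm)
    r = np.hypot(X, Y)
    theta = np.degrees(np.arctan2(Y, X)) % 360.0

    sector = np.zeros(r.shape, dtype=int)  # offsets: sup 0, nasal 1, inf 2, temp 3
    sector[(theta >= 45.0) & (theta < 135.0)] = 0
    sector[(theta >= 135.0) & (theta < 225.0)] = 3
    sector[(theta >= 225.0) & (theta < 315.0)] = 2
    sector[(theta >= 315.0) | (theta < 45.0)] = 1

    labels = np.zeros(r.shape, dtype=int)
    labels[r < radii_mm[0]] = FOVEAL
    inner = (r >= radii_mm[0]) & (r < radii_mm[1])
    outer = (r >= radii_mm[1]) & (r < radii_mm[2])
    labels[inner] = 2 + sector[inner]
    labels[outer] = 6 + sector[outer]
    return EtdrsLabels(labels=labels, extent_mm=extent_mm, radii_mm=radii_mm)


def region_areas(labels: EtdrsLabels) -> pd.Series:
    """Discretized area of each subfield in mm² (cell count x cell area)."""
    areas = {
        REGION_NAMES[lab]: float((labels.labels == lab).sum()) * labels.cell_area_mm2
        for lab in REGION_LABELS
    }
    return pd.Series(areas, name="area_mm2")


def _check_geometry(grid: StandardGrid, labels: EtdrsLabels) -> None:
    if grid.grid.shape != labels.labels.shape:
        raise ValueError("standard grid and ETDRS labels have mismatched shapes")
    if not np.isclose(grid.extent_mm, labels.extent_mm):
        raise ValueError("standard grid and ETDRS labels have mismatched extents")


def region_means(
    grid: StandardGrid, labels: EtdrsLabels, skip_fill: bool = False
) -> pd.Series:
    """Mean probability of a feature within each of the nine subfields.

    With ``skip_fill`` the fill-valued cells (outside the scanned field)
    are excluded from the averages; a subfield with no remaining cells
    yields NaN.
    """
    _check_geometry(grid, labels)
    valid = np.ones(grid.grid.shape, dtype=bool)
    if skip_fill:
        valid = grid.grid != grid.fill_value
    means = {}
    for lab in REGION_LABELS:
        sel = (labels.labels == lab) & valid
        means[REGION_NAMES[lab]] = float(grid.grid[sel].mean()) if sel.any() else np.nan
    return pd.Series(means, name="mean_probability")


def foveal_involvement(
    rora: StandardGrid, labels: EtdrsLabels, threshold: float = 0.5
) -> bool:
    """Whether RORA touches the central 1-mm foveal disc.

    True iff any foveal-subfield cell carries probability >= threshold.
    Eyes where this is False are *foveal sparing*.
    """
    _check_geometry(rora, labels)
    sel = labels.labels == FOVEAL
    return bool((rora.grid[sel] >= threshold).any())


def area_in_regions(
    grid: StandardGrid,
    labels: EtdrsLabels,
    threshold: float = 0.5,
    regions: Optional[Iterable[int]] = None,
) -> float:
    """Thresholded lesion area (mm²) restricted to a set of subfield labels.

    ``regions=None`` counts every cell; pass e.g. all labels except
    :data:`FOVEAL` for the extrafoveal lesion area.
    """
    _check_geometry(grid, labels)
    mask = grid.grid >= threshold
    if regions is not None:
        mask &= np.isin(labels.labels, list(regions))
    return float(mask.sum()) * grid.cell_area_mm2


def extrafoveal_area(
    grid: StandardGrid, labels: EtdrsLabels, threshold: float = 0.5
) -> float:
    """Thresholded lesion area outside the foveal subfield, in mm²."""
    _check_geometry(grid, labels)
    mask = (grid.grid >= threshold) & (labels.labels != FOVEAL)
    return float(mask.sum()) * grid.cell_area_mm2
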