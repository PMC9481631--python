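"""En-face reduction of OCT segmentation probability volumes.

A macular OCT volume is a stack of cross-sectional b-scans, each made of
vertical depth columns (A-scans). Lesion-segmentation models emit a
probability per pixel (or directly per A-scan) for each morphological
feature of geographic atrophy: loss of the retinal pigment epithelium
(RPE-loss), photoreceptor degeneration, and choroidal hypertransmission.

This module collapses those volumes to two-dimensional *en-face* maps with
one probability per A-scan, derives RPE-and-outer-retinal atrophy (RORA)
as the per-A-scan co-occurrence of all three constituent features, and
measures thresholded lesion areas in mm².

Conventions
-----------
* rows index b-scans (row 0 = superior edge of the field), columns index
  A-scans within a b-scan;
* map coordinates are millimetres from the top-left corner of the scanned
  field, ``x`` along columns and ``y`` along rows;
* a feature is called *present* at a cell when its probability is greater
  than or equal to the binarization threshold (default 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Tuple

import numpy as np

#: Minimum number of b-scans for a volume to be considered a valid dense
#: macular raster (coarser volumes cannot support per-A-scan mapping).
MIN_BSCANS = 25

#: Default probability threshold for feature presence.
DEFAULT_THRESHOLD = 0.5


class Feature(str, Enum):
    """Morphological features of geographic atrophy on OCT."""

    RPE_LOSS = "rpe_loss"
    PDR = "photoreceptor_degeneration"
    HYPERTRANSMISSION = "hypertransmission"
    #: derived feature: co-occurrence of the three raw features
    RORA = "rora"


#: The three independently segmented features.
RAW_FEATURES: Tuple[Feature, ...] = (
    Feature.RPE_LOSS,
    Feature.PDR,
    Feature.HYPERTRANSMISSION,
)

#: Raw features plus derived RORA, in canonical order.
ALL_FEATURES: Tuple[Feature, ...] = RAW_FEATURES + (Feature.RORA,)


class Laterality(str, Enum):
    OD = "OD"  #: right eye
    OS = "OS"  #: left eye


def _check_probabilities(a: np.ndarray, what: str) -> None:
    if a.size and (np.nanmin(a) < 0.0 or np.nanmax(a) > 1.0):
        raise ValueError(f"{what} must lie in [0, 1]")


@dataclass
class SegVolume:
    """Per-feature segmentation output for one eye.

    Parameters
    ----------
    feature
        Which lesion feature the probabilities describe.
    data
        ``(n_bscans, n_ascans)`` array of per-A-scan probabilities, or
        ``None`` when only per-b-scan pixel masks are available.
    laterality
        ``OD`` (right) or ``OS`` (left); needed later for nasal/temporal
        normalization.
    fovea_xy_mm
        Manually annotated foveal centre, in mm from the top-left corner
        of the field (x along A-scans, y along b-scans).
    field_mm
        Physical extent of the raster, ``(height, width)`` in mm.
    bscan_masks
        Optional ``(n_bscans, depth, n_ascans)`` per-pixel probabilities;
        when given, :func:`build_enface` reduces each depth column with the
        max rule.
    """

    feature: Feature
    data: Optional[np.ndarray]
    laterality: Laterality
    fovea_xy_mm: Tuple[float, float]
    field_mm: Tuple[float, float] = (6.0, 6.0)
    bscan_masks: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.feature = Feature(self.feature)
        self.laterality = Laterality(self.laterality)
        if self.data is None and self.bscan_masks is None:
            raise ValueError("SegVolume needs data or bscan_masks")
        if self.data is not None:
            self.data = np.asarray(self.data, dtype=float)
            if self.data.ndim != 2:
                raise ValueError("data must be 2-D (n_bscans, n_ascans)")
            _check_probabilities(self.data, "segmentation probabilities")
        if self.bscan_masks is not None:
            self.bscan_masks = np.asarray(self.bscan_masks, dtype=float)
            if self.bscan_masks.ndim != 3:
                raise ValueError("bscan_masks must be 3-D (n_bscans, depth, n_ascans)")
            _check_probabilities(self.bscan_masks, "segmentation probabilities")
            if self.data is not None and self.data.shape != (
                self.bscan_masks.shape[0],
                self.bscan_masks.shape[2],
            ):
                raise ValueError("data and bscan_masks shapes disagree")
        if self.n_bscans < MIN_BSCANS:
            raise ValueError(
                f"volume has {self.n_bscans} b-scans; at least {MIN_BSCANS} required"
            )
        if min(self.field_mm) <= 0:
            raise ValueError("field_mm must be positive")

    @property
    def n_bscans(self) -> int:
        src = self.data if self.data is not None else self.bscan_masks
        return int(src.shape[0])

    @property
    def n_ascans(self) -> int:
        if self.data is not None:
            return int(self.data.shape[1])
        return int(self.bscan_masks.shape[2])


@dataclass
class EnFaceMap:
    """Two-dimensional per-A-scan probability map of one feature.

    ``grid[i, j]`` is the probability that the feature is present in
    A-scan ``j`` of b-scan ``i``. ``spacing_mm`` is the (row, col) cell
    pitch and ``fovea_xy_mm`` the annotated foveal centre in map
    coordinates.
    """

    feature: Feature
    grid: np.ndarray
    spacing_mm: Tuple[float, float]
    fovea_xy_mm: Tuple[float, float]
    laterality: Laterality

    def __post_init__(self) -> None:
        self.feature = Feature(self.feature)
        self.laterality = Laterality(self.laterality)
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2-D")
        _check_probabilities(self.grid, "en-face probabilities")

    @property
    def field_mm(self) -> Tuple[float, float]:
        """Physical (height, width) of the mapped field in mm."""
        return (
            self.grid.shape[0] * self.spacing_mm[0],
            self.grid.shape[1] * self.spacing_mm[1],
        )

    @property
    def cell_area_mm2(self) -> float:
        return float(self.spacing_mm[0] * self.spacing_mm[1])


def reduce_column(
    pixel_column: np.ndarray, threshold: float = DEFAULT_THRESHOLD
) -> Tuple[float, bool]:
    """Collapse one A-scan pixel column to a presence probability.

    The probability is the column maximum — the reduction consistent with
    detecting *presence anywhere in depth* — and the binary label applies
    the ``>= threshold`` convention.

    Returns
    -------
    (probability, present)
    """
    col = np.asarray(pixel_column, dtype=float)
    if col.size == 0:
        raise ValueError("empty A-scan column")
    _check_probabilities(col, "pixel column")
    p = float(col.max())
    return p, bool(p >= threshold)


def build_enface(volume: SegVolume) -> EnFaceMap:
    """Project a segmentation volume onto the en-face plane.

    If the volume carries per-b-scan pixel masks, every depth column is
    reduced with the max rule of :func:`reduce_column`; a volume already
    at A-scan resolution passes through unchanged. Spacing, laterality and
    the foveal annotation are carried over.
    """
    if volume.bscan_masks is not None:
        grid = volume.bscan_masks.max(axis=1)
    else:
        grid = volume.data.copy()
    h_mm, w_mm = volume.field_mm
    fx, fy = volume.fovea_xy_mm
    if not (0.0 <= fx <= w_mm and 0.0 <= fy <= h_mm):
        raise ValueError(
            f"fovea annotation ({fx:.2f}, {fy:.2f}) mm outside the "
            f"{h_mm:.1f} x {w_mm:.1f} mm field"
        )
    spacing = (h_mm / grid.shape[0], w_mm / grid.shape[1])
    return EnFaceMap(
        feature=volume.feature,
        grid=grid,
        spacing_mm=spacing,
        fovea_xy_mm=volume.fovea_xy_mm,
        laterality=volume.laterality,
    )


def _check_same_geometry(maps: Tuple[EnFaceMap, ...]) -> None:
    ref = maps[0]
    for m in maps[1:]:
        if m.grid.shape != ref.grid.shape:
            raise ValueError("en-face maps have mismatched grid shapes")
        if not np.allclose(m.spacing_mm, ref.spacing_mm):
            raise ValueError("en-face maps have mismatched spacing")
        if m.laterality != ref.laterality:
            raise ValueError("en-face maps have mismatched laterality")


def derive_rora(rpe: EnFaceMap, pdr: EnFaceMap, ht: EnFaceMap) -> EnFaceMap:
    """Derive RORA as the per-A-scan co-occurrence of all three features.

    The probabilistic map is the cell-wise minimum (fuzzy AND), the unique
    reduction whose thresholding commutes with the binary definition: the
    minimum exceeds ``t`` exactly where all three constituents do. RORA is
    therefore always a subset of each constituent at every threshold.
    """
    _check_same_geometry((rpe, pdr, ht))
    grid = np.minimum(np.minimum(rpe.grid, pdr.grid), ht.grid)
    return EnFaceMap(
        feature=Feature.RORA,
        grid=grid,
        spacing_mm=rpe.spacing_mm,
        fovea_xy_mm=rpe.fovea_xy_mm,
        laterality=rpe.laterality,
    )


def binarize(emap: EnFaceMap, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Boolean presence mask at the given probability threshold."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie strictly in (0, 1)")
    return emap.grid >= threshold


def lesion_area(emap: EnFaceMap, threshold: float = DEFAULT_THRESHOLD) -> float:
    """Thresholded lesion area in mm² (cell counting, no sub-cell geometry)."""
    return float(binarize(emap, threshold).sum()) * emap.cell_area_mm2
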