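"""Voxel-grid, contour, sector, and perfusion-territory geometry.

Conventions used throughout the package:

* Volumes are indexed ``(slice, row, col)``; slices are ordered base -> apex.
* In-plane positions are in millimetres.  The centre of pixel ``(r, c)`` sits
  at ``(x, y) = (c * s, r * s)`` where ``s`` is the (isotropic) in-plane
  spacing.  Contour polygons are point lists in these mm coordinates.
* Angles are in degrees, measured counterclockwise in the ``(x, y)`` plane.
* The myocardial circumference is divided into 24 sectors of 15 degrees.
  Sector 0 starts at the anterior right-ventricular (RV) insertion angle and
  indices increase counterclockwise.  Sector bins are half-open
  ``[a, a + 15)``; a voxel exactly on a boundary gets the lower index.
* Slice levels (basal / mid / apical = 0 / 1 / 2) are assigned by thirds of
  the delineated slice range.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
from matplotlib.path import Path

N_SECTORS = 24
SECTOR_WIDTH_DEG = 360.0 / N_SECTORS
ARTERIES = ("LAD", "LCx", "RCA", "LM")
LEVELS = ("basal", "mid", "apical")
TIMEFRAMES = ("ED", "ES")


class ContourError(ValueError):
    """Raised for malformed or inconsistent contour input."""


@dataclass(frozen=True)
class VoxelGrid:
    """Regular short-axis image grid.

    Parameters are in voxels (``rows``, ``cols``, ``n_slices``) and
    millimetres (``in_plane_spacing`` per pixel, isotropic; ``slice_thickness``
    including any gap — the study protocol this emulates uses 8 mm contiguous
    slices at 1.5 x 1.5 mm in-plane).
    """

    rows: int
    cols: int
    n_slices: int
    in_plane_spacing: float = 1.5
    slice_thickness: float = 8.0

    def __post_init__(self) -> None:
        if min(self.rows, self.cols, self.n_slices) < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.in_plane_spacing <= 0 or self.slice_thickness <= 0:
            raise ValueError("grid spacings must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_slices, self.rows, self.cols)

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        return self.in_plane_spacing**2 * self.slice_thickness

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) mm coordinates of in-plane pixel centres, shape (rows, cols)."""
        s = self.in_plane_spacing
        y, x = np.mgrid[0 : self.rows, 0 : self.cols]
        return x * s, y * s


@dataclass(frozen=True)
class SliceContours:
    """Endocardial and epicardial polygons for one slice (mm coordinates)."""

    endo: np.ndarray
    epi: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "endo", _as_polygon(self.endo, "endocardial"))
        object.__setattr__(self, "epi", _as_polygon(self.epi, "epicardial"))


# ContourSet: {timeframe: {slice index: SliceContours}}
ContourSet = Mapping[str, Mapping[int, SliceContours]]


def _as_polygon(points, name: str) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ContourError(f"{name} polygon must be an (N, 2) point list")
    if not np.all(np.isfinite(pts)):
        raise ContourError(f"{name} polygon contains non-finite coordinates")
    # a trailing repeat of the first vertex is accepted and dropped
    if len(pts) > 1 and np.array_equal(pts[0], pts[-1]):
        pts = pts[:-1]
    if len(pts) < 3:
        raise ContourError(f"{name} polygon is open/degenerate (< 3 vertices)")
    return pts


def polygon_mask(points: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    """Boolean (rows, cols) mask of pixels whose centres lie inside the polygon."""
    pts = _as_polygon(points, "input")
    x, y = grid.pixel_centers()
    centers = np.column_stack([x.ravel(), y.ravel()])
    inside = Path(pts).contains_points(centers)  # implicitly closed polygon
    return inside.reshape(grid.rows, grid.cols)


def rasterize_contours(contours: ContourSet, grid: VoxelGrid, timeframe: str) -> np.ndarray:
    """Rasterize endo/epicardial contours into a myocardial mask.

    Returns a boolean ``(n_slices, rows, cols)`` array, true exactly for
    pixels whose centres lie inside the epicardium and outside the
    endocardium.  Slices without contours are empty.
    """
    if timeframe not in contours:
        raise ContourError(f"timeframe {timeframe!r} not delineated")
    mask = np.zeros(grid.shape, dtype=bool)
    for s, sc in contours[timeframe].items():
        if not 0 <= s < grid.n_slices:
            raise ContourError(f"contour slice index {s} outside grid")
        epi = polygon_mask(sc.epi, grid)
        endo = polygon_mask(sc.endo, grid)
        if (endo & ~epi).any():
            raise ContourError(
                f"slice {s}: endocardium not strictly contained in epicardium"
            )
        mask[s] = epi & ~endo
    return mask


def endo_centroids(contours: ContourSet, timeframe: str) -> dict[int, tuple[float, float]]:
    """Per-slice LV centre: vertex centroid of the endocardial polygon (mm)."""
    return {
        s: (float(sc.endo[:, 0].mean()), float(sc.endo[:, 1].mean()))
        for s, sc in contours[timeframe].items()
    }


def slice_levels(delineated: np.ndarray) -> np.ndarray:
    """Assign basal/mid/apical (0/1/2) levels by thirds of the delineated range.

    ``delineated`` is a boolean (n_slices,) array; non-delineated slices get -1.
    """
    delineated = np.asarray(delineated, dtype=bool)
    levels = np.full(delineated.shape, -1, dtype=np.int8)
    idx = np.flatnonzero(delineated)
    if idx.size:
        ranks = np.arange(idx.size)
        levels[idx] = np.minimum(2, (3 * ranks) // idx.size)
    return levels


def sector_of_angle(theta_deg: np.ndarray, rv_anterior_deg: float) -> np.ndarray:
    """Sector index for angles ``theta_deg``, counterclockwise from the RV insertion."""
    rel = np.mod(np.asarray(theta_deg, dtype=float) - rv_anterior_deg, 360.0)
    return np.minimum((rel / SECTOR_WIDTH_DEG).astype(np.int16), N_SECTORS - 1)


@dataclass
class SectorMap:
    """Per-voxel circumferential sector labels for one timeframe.

    ``labels`` is ``(n_slices, rows, cols)`` int16 with sector index 0..23 on
    myocardial voxels and -1 elsewhere; ``levels`` is the per-slice
    basal/mid/apical assignment (-1 for slices without myocardium).
    """

    labels: np.ndarray
    levels: np.ndarray
    rv_anterior_deg: float


def divide_sectors(
    mask: np.ndarray,
    centroids: Mapping[int, tuple[float, float]],
    rv_anterior_deg: float,
    grid: VoxelGrid,
) -> SectorMap:
    """Divide the myocardium into 24 circumferential sectors.

    Each myocardial voxel is labelled by the 15-degree angular bin of its
    centre about the per-slice LV centroid, counted counterclockwise from the
    anterior RV insertion angle.
    """
    if not 0 <= rv_anterior_deg < 360:
        raise ValueError("RV insertion angle must lie in [0, 360)")
    mask = np.asarray(mask, dtype=bool)
    labels = np.full(mask.shape, -1, dtype=np.int16)
    x, y = grid.pixel_centers()
    for s in range(mask.shape[0]):
        m = mask[s]
        if not m.any():
            if s in centroids:
                warnings.warn(f"slice {s}: empty myocardial mask, skipped")
            continue
        if s not in centroids:
            raise ValueError(f"slice {s}: no centroid for non-empty mask")
        cx, cy = centroids[s]
        rr, cc = np.nonzero(m)
        if not (
            x[rr, cc].min() <= cx <= x[rr, cc].max()
            and y[rr, cc].min() <= cy <= y[rr, cc].max()
        ):
            raise ValueError(f"slice {s}: centroid outside mask bounding box")
        theta = np.degrees(np.arctan2(y[rr, cc] - cy, x[rr, cc] - cx))
        labels[s, rr, cc] = sector_of_angle(theta, rv_anterior_deg)
    return SectorMap(labels=labels, levels=slice_levels(mask.any(axis=(1, 2))),
                     rv_anterior_deg=rv_anterior_deg)


# ---------------------------------------------------------------------------
# Maximal extent models (a priori perfusion territories)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaximalExtentModel:
    """A priori maximal perfusion territory of a culprit coronary artery.

    ``coverage`` is boolean (3 levels, 24 sectors): which circumferential
    sectors can belong to the myocardium at risk of a proximal occlusion at
    each slice level.  Sector indexing follows :class:`SectorMap`.
    """

    artery: str
    coverage: np.ndarray

    def __post_init__(self) -> None:
        cov = np.asarray(self.coverage, dtype=bool)
        if cov.shape != (len(LEVELS), N_SECTORS):
            raise ValueError("coverage must be (3, 24)")
        if not cov.any(axis=1).all():
            raise ValueError("every level must cover at least one sector")
        for row in cov:
            if not _is_circularly_contiguous(row):
                raise ValueError("territory sectors must be circumferentially contiguous")
        object.__setattr__(self, "coverage", cov)


def _is_circularly_contiguous(flags: np.ndarray) -> bool:
    flags = np.asarray(flags, dtype=bool)
    if flags.all() or not flags.any():
        return flags.any()
    # number of False->True transitions around the circle must be exactly one
    rolled = np.roll(flags, 1)
    return int((flags & ~rolled).sum()) == 1


def _load_territory_table(path=None) -> dict:
    if path is None:
        with resources.files("marquant.data").joinpath("territories.json").open() as fh:
            return json.load(fh)
    with open(path) as fh:
        return json.load(fh)


def build_maximal_extent(culprit: str, table_path=None) -> MaximalExtentModel:
    """Look up the configured maximal-extent territory for a culprit artery.

    The default table ships with the package (AHA-style artery/sector
    assignment dilated by one sector per circumferential edge); the left main
    (LM) territory is the union of LAD and LCx.  Users may supply their own
    JSON table via ``table_path``.
    """
    if culprit not in ARTERIES:
        raise ValueError(f"unknown culprit artery {culprit!r}; expected one of {ARTERIES}")
    table = _load_territory_table(table_path)
    if culprit == "LM":
        lad = build_maximal_extent("LAD", table_path)
        lcx = build_maximal_extent("LCx", table_path)
        return MaximalExtentModel("LM", lad.coverage | lcx.coverage)
    cov = np.zeros((len(LEVELS), N_SECTORS), dtype=bool)
    for i, level in enumerate(LEVELS):
        cov[i, np.asarray(table[culprit][level], dtype=int)] = True
    return MaximalExtentModel(culprit, cov)


def extent_region(sector_map: SectorMap, extent: MaximalExtentModel) -> np.ndarray:
    """Mask of myocardial voxels inside the culprit territory."""
    return _region_from_extent(sector_map, extent, inside=True)


def remote_region(sector_map: SectorMap, extent: MaximalExtentModel) -> np.ndarray:
    """Mask of myocardial voxels outside the culprit territory (remote).

    Remote intensity statistics are undefined when the territory covers the
    whole circumference at some level present in the study; that is an error.
    """
    for lvl in np.unique(sector_map.levels[sector_map.levels >= 0]):
        if extent.coverage[lvl].all():
            raise ValueError(
                f"territory covers all {N_SECTORS} sectors at level {LEVELS[lvl]}; "
                "remote region undefined"
            )
    return _region_from_extent(sector_map, extent, inside=False)


def _region_from_extent(sector_map: SectorMap, extent: MaximalExtentModel,
                        inside: bool) -> np.ndarray:
    labels, levels = sector_map.labels, sector_map.levels
    out = np.zeros(labels.shape, dtype=bool)
    for s in range(labels.shape[0]):
        if levels[s] < 0:
            continue
        covered = extent.coverage[levels[s]]
        myo = labels[s] >= 0
        sel = covered[labels[s][myo]]
        out[s][myo] = sel if inside else ~sel
    return out


def extent_center_sector(extent: MaximalExtentModel, level: int) -> float:
    """Angular centre (fractional sector index) of the territory at a level."""
    flags = extent.coverage[level]
    if flags.all():
        return 0.0
    start = int(np.flatnonzero(flags & ~np.roll(flags, 1))[0])
    length = int(flags.sum())
    return (start + length / 2.0) % N_SECTORS
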