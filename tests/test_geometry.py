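"""Contour rasterization, sector division, and perfusion-territory geometry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import Point, Polygon

from marquant.geometry import (
    ARTERIES,
    ContourError,
    N_SECTORS,
    SliceContours,
    VoxelGrid,
    build_maximal_extent,
    divide_sectors,
    extent_region,
    rasterize_contours,
    remote_region,
    sector_of_angle,
    slice_levels,
)
from conftest import circle


class TestRasterize:
    def test_annulus_area_matches_analytic(self, annulus_grid, annulus_contours):
        mask = rasterize_contours(annulus_contours, annulus_grid, "ED")
        area = mask.sum() * annulus_grid.in_plane_spacing**2
        expected = np.pi * (30.0**2 - 20.0**2)
        assert abs(area - expected) / expected < 0.02

    def test_zero_thickness_wall_is_empty(self, annulus_grid):
        c = (annulus_grid.cols - 1) / 2 * annulus_grid.in_plane_spacing
        contours = {"ED": {0: SliceContours(endo=circle(c, c, 25.0),
                                            epi=circle(c, c, 25.0))}}
        assert rasterize_contours(contours, annulus_grid, "ED").sum() == 0

    def test_endo_outside_epi_raises(self, annulus_grid):
        c = (annulus_grid.cols - 1) / 2 * annulus_grid.in_plane_spacing
        contours = {"ED": {0: SliceContours(endo=circle(c + 20, c, 20.0),
                                            epi=circle(c, c, 30.0))}}
        with pytest.raises(ContourError, match="contained"):
            rasterize_contours(contours, annulus_grid, "ED")

    def test_open_polygon_raises(self):
        with pytest.raises(ContourError, match="open|degenerate"):
            SliceContours(endo=np.array([[0.0, 0.0], [1.0, 0.0]]),
                          epi=circle(10, 10, 5))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_point_in_polygon_oracle(self, seed):
        """Pixel-centre classification agrees with an independent geometric oracle
        (shapely) on random star-convex polygons."""
        rng = np.random.default_rng(seed)
        grid = VoxelGrid(rows=40, cols=40, n_slices=1, in_plane_spacing=1.0)
        cx = cy = 19.5
        n = rng.integers(5, 16)
        ang = np.sort(rng.uniform(0, 2 * np.pi, n))
        r_out = rng.uniform(10, 18, n)
        epi = np.column_stack([cx + r_out * np.cos(ang), cy + r_out * np.sin(ang)])
        endo = np.column_stack([cx + 0.4 * r_out * np.cos(ang),
                                cy + 0.4 * r_out * np.sin(ang)])
        contours = {"ED": {0: SliceContours(endo=endo, epi=epi)}}
        mask = rasterize_contours(contours, grid, "ED")[0]
        poly_epi, poly_endo = Polygon(epi), Polygon(endo)
        x, y = grid.pixel_centers()
        oracle = np.array([poly_epi.contains(Point(px, py))
                           and not poly_endo.contains(Point(px, py))
                           for px, py in zip(x.ravel(), y.ravel())]).reshape(mask.shape)
        assert (mask == oracle).all()


class TestSectors:
    def test_full_annulus_has_24_labels(self, annulus_grid, annulus_contours):
        mask = rasterize_contours(annulus_contours, annulus_grid, "ED")
        c = (annulus_grid.cols - 1) / 2 * annulus_grid.in_plane_spacing
        smap = divide_sectors(mask, {0: (c, c)}, 100.0, annulus_grid)
        labels = smap.labels[0][mask[0]]
        assert len(np.unique(labels)) == N_SECTORS

    def test_label_histogram_approximately_uniform(self, annulus_grid, annulus_contours):
        mask = rasterize_contours(annulus_contours, annulus_grid, "ED")
        c = (annulus_grid.cols - 1) / 2 * annulus_grid.in_plane_spacing
        smap = divide_sectors(mask, {0: (c, c)}, 0.0, annulus_grid)
        counts = np.bincount(smap.labels[0][mask[0]], minlength=N_SECTORS)
        assert np.all(np.abs(counts - counts.mean()) <= 0.2 * counts.mean())

    def test_rotating_insertion_shifts_labels(self, annulus_grid, annulus_contours):
        mask = rasterize_contours(annulus_contours, annulus_grid, "ED")
        c = (annulus_grid.cols - 1) / 2 * annulus_grid.in_plane_spacing
        a = divide_sectors(mask, {0: (c, c)}, 30.0, annulus_grid)
        b = divide_sectors(mask, {0: (c, c)}, 45.0, annulus_grid)
        myo = mask[0]
        assert np.array_equal(b.labels[0][myo], (a.labels[0][myo] - 1) % N_SECTORS)

    def test_half_open_boundary_convention(self):
        # a point exactly on the k*15 deg boundary starts sector k
        assert sector_of_angle(np.array([15.0]), 0.0)[0] == 1
        assert sector_of_angle(np.array([15.0 - 1e-9]), 0.0)[0] == 0
        assert sector_of_angle(np.array([360.0]), 0.0)[0] == 0

    def test_centroid_outside_mask_raises(self, annulus_grid, annulus_contours):
        mask = rasterize_contours(annulus_contours, annulus_grid, "ED")
        with pytest.raises(ValueError, match="bounding box"):
            divide_sectors(mask, {0: (1000.0, 1000.0)}, 0.0, annulus_grid)

    def test_slice_levels_by_thirds(self):
        levels = slice_levels(np.array([False] + [True] * 8))
        assert levels[0] == -1
        assert levels.tolist()[1:] == [0, 0, 0, 1, 1, 1, 2, 2]


class TestMaximalExtent:
    def test_lm_is_union_of_lad_and_lcx(self):
        lad = build_maximal_extent("LAD").coverage
        lcx = build_maximal_extent("LCx").coverage
        lm = build_maximal_extent("LM").coverage
        assert np.array_equal(lm, lad | lcx)

    @pytest.mark.parametrize("artery", ARTERIES)
    def test_every_level_covered_and_contiguous(self, artery):
        cov = build_maximal_extent(artery).coverage
        assert cov.any(axis=1).all()  # >= 1 sector at every level
        for row in cov:
            idx = np.flatnonzero(row)
            gaps = int((row & ~np.roll(row, 1)).sum())
            assert gaps == 1 or row.all()
            assert idx.size >= 1

    def test_lad_mid_includes_sector_adjacent_to_insertion(self):
        # sector 0 is immediately counterclockwise of the anterior RV insertion
        assert build_maximal_extent("LAD").coverage[1, 0]

    def test_unknown_artery_raises(self):
        with pytest.raises(ValueError, match="unknown culprit"):
            build_maximal_extent("XYZ")


class TestRemoteRegion:
    def _sector_map(self, annulus_grid, annulus_contours):
        mask = rasterize_contours(annulus_contours, annulus_grid, "ED")
        c = (annulus_grid.cols - 1) / 2 * annulus_grid.in_plane_spacing
        return mask, divide_sectors(mask, {0: (c, c)}, 120.0, annulus_grid)

    def test_partition_of_myocardium(self, annulus_grid, annulus_contours):
        mask, smap = self._sector_map(annulus_grid, annulus_contours)
        extent = build_maximal_extent("LAD")
        remote = remote_region(smap, extent)
        inside = extent_region(smap, extent)
        assert not (remote & inside).any()
        assert np.array_equal(remote | inside, mask)

    def test_remote_sector_count(self, annulus_grid, annulus_contours):
        _, smap = self._sector_map(annulus_grid, annulus_contours)
        extent = build_maximal_extent("LAD")
        remote = remote_region(smap, extent)
        k = int(extent.coverage[0].sum())
        assert len(np.unique(smap.labels[0][remote[0]])) == N_SECTORS - k

    def test_full_coverage_extent_raises(self, annulus_grid, annulus_contours):
        from marquant.geometry import MaximalExtentModel
        _, smap = self._sector_map(annulus_grid, annulus_contours)
        full = MaximalExtentModel("LAD", np.ones((3, N_SECTORS), dtype=bool))
        with pytest.raises(ValueError, match="remote region undefined"):
            remote_region(smap, full)
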