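import numpy as np
import pytest

from gafunc.enface import EnFaceMap, Feature, Laterality
from gafunc.grid import (
    FOVEAL,
    INNER_SUPERIOR,
    OUTER_NASAL,
    REGION_LABELS,
    REGION_NAMES,
    StandardGrid,
    area_in_regions,
    cell_centers,
    etdrs_labels,
    extrafoveal_area,
    foveal_involvement,
    region_areas,
    region_means,
    standardize,
)

from conftest import random_enface


def toy_map(grid, fovea, laterality="OD", field_mm=6.0, feature=Feature.RORA):
    grid = np.asarray(grid, dtype=float)
    spacing = (field_mm / grid.shape[0], field_mm / grid.shape[1])
    return EnFaceMap(
        feature=feature,
        grid=grid,
        spacing_mm=spacing,
        fovea_xy_mm=fovea,
        laterality=laterality,
    )


class TestEtdrsLabels:
    def test_centre_cell_is_foveal(self):
        labels = etdrs_labels((49, 49), 3.0)
        assert labels.labels[24, 24] == FOVEAL

    def test_one_mm_superior_is_inner_superior(self):
        labels = etdrs_labels((49, 49), 3.0)
        X, Y = cell_centers((49, 49), 3.0)
        i, j = 16, 24  # centre (0, +0.98) mm: radius in [0.5, 1.5), angle 90 deg
        assert abs(X[i, j]) < 1e-9 and 0.5 <= Y[i, j] < 1.5
        assert labels.labels[i, j] == INNER_SUPERIOR

    def test_labels_partition_grid(self):
        labels = etdrs_labels((30, 30), 3.0)
        assert set(np.unique(labels.labels)) <= set(range(10))
        counts = [(labels.labels == lab).sum() for lab in range(10)]
        assert sum(counts) == 30 * 30

    def test_labels_match_polar_definition(self):
        labels = etdrs_labels((33, 33), 3.0)
        X, Y = cell_centers((33, 33), 3.0)
        r = np.hypot(X, Y)
        np.testing.assert_array_equal(labels.labels == FOVEAL, r < 0.5)
        np.testing.assert_array_equal(labels.labels == 0, r >= 3.0)

    def test_discretized_areas_converge_to_analytic(self):
        labels = etdrs_labels((490, 490), 3.0)
        areas = region_areas(labels)
        assert areas["foveal"] == pytest.approx(np.pi * 0.25, abs=5e-3)
        inner = np.pi * (1.5**2 - 0.5**2) / 4  # 1.571 mm2 per quadrant
        outer = np.pi * (3.0**2 - 1.5**2) / 4  # 5.301 mm2 per quadrant
        for name in ("inner_superior", "inner_nasal", "inner_inferior", "inner_temporal"):
            assert areas[name] == pytest.approx(inner, rel=0.01)
        for name in ("outer_superior", "outer_nasal", "outer_inferior", "outer_temporal"):
            assert areas[name] == pytest.approx(outer, rel=0.01)


class TestStandardize:
    def test_identity_when_fovea_at_centre(self):
        rng = np.random.default_rng(0)
        grid = rng.random((49, 49))
        emap = toy_map(grid, fovea=(3.0, 3.0))
        sg = standardize(emap, (49, 49), 3.0)
        np.testing.assert_allclose(sg.grid, grid, atol=1e-12)

    def test_os_map_matches_mirrored_od_map(self):
        rng = np.random.default_rng(1)
        grid = rng.random((21, 21))
        fovea = (2.2, 3.4)
        os_map = toy_map(grid, fovea=fovea, laterality="OS")
        od_map = toy_map(grid[:, ::-1], fovea=(6.0 - fovea[0], fovea[1]),
                         laterality="OD")
        sg_os = standardize(os_map, (21, 21), 3.0)
        sg_od = standardize(od_map, (21, 21), 3.0)
        np.testing.assert_array_equal(sg_os.grid, sg_od.grid)

    def test_one_cell_fovea_offset_shifts_grid(self):
        rng = np.random.default_rng(2)
        grid = rng.random((9, 9))
        cell = 6.0 / 9
        emap = toy_map(grid, fovea=(3.0 + cell, 3.0))
        sg = standardize(emap, (9, 9), 3.0, fill_value=0.0)
        # interior equals the source shifted one cell left
        np.testing.assert_allclose(sg.grid[:, :-1], grid[:, 1:], atol=1e-12)
        # vacated boundary column filled
        np.testing.assert_allclose(sg.grid[:, -1], 0.0)

    def test_missing_fovea_or_laterality_rejected(self):
        emap = toy_map(np.zeros((9, 9)), fovea=(3, 3))
        emap.fovea_xy_mm = None
        with pytest.raises(ValueError):
            standardize(emap)
        emap2 = toy_map(np.zeros((9, 9)), fovea=(9.0, 3.0))
        with pytest.raises(ValueError):
            standardize(emap2)

    def test_mirror_equivariance_on_random_maps(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            m = random_enface(rng, shape=(25, 25), laterality=Laterality.OS,
                              fovea=(2.8, 3.2))
            mirrored = EnFaceMap(
                feature=m.feature,
                grid=m.grid[:, ::-1],
                spacing_mm=m.spacing_mm,
                fovea_xy_mm=(m.field_mm[1] - m.fovea_xy_mm[0], m.fovea_xy_mm[1]),
                laterality=Laterality.OD,
            )
            np.testing.assert_array_equal(
                standardize(m, (25, 25)).grid, standardize(mirrored, (25, 25)).grid
            )


class TestRegionSummaries:
    def test_constant_field_means(self):
        labels = etdrs_labels((49, 49), 3.0)
        sg = StandardGrid(np.full((49, 49), 0.7), 3.0)
        means = region_means(sg, labels)
        assert np.allclose(means.to_numpy(), 0.7)

    def test_zero_field_means(self):
        labels = etdrs_labels((49, 49), 3.0)
        means = region_means(StandardGrid(np.zeros((49, 49)), 3.0), labels)
        assert np.allclose(means.to_numpy(), 0.0)

    def test_foveal_disc_isolated(self):
        labels = etdrs_labels((49, 49), 3.0)
        X, Y = cell_centers((49, 49), 3.0)
        grid = (np.hypot(X, Y) < 0.5).astype(float)
        means = region_means(StandardGrid(grid, 3.0), labels)
        assert means["foveal"] == pytest.approx(1.0)
        assert np.allclose(means.drop("foveal").to_numpy(), 0.0)

    def test_foveal_involvement(self):
        labels = etdrs_labels((49, 49), 3.0)
        zero = StandardGrid(np.zeros((49, 49)), 3.0)
        assert not foveal_involvement(zero, labels, 0.5)
        one = np.zeros((49, 49))
        one[24, 24] = 0.9
        assert foveal_involvement(StandardGrid(one, 3.0), labels, 0.5)

    def test_extrafoveal_area_excludes_fovea(self):
        labels = etdrs_labels((49, 49), 3.0)
        sg = StandardGrid(np.ones((49, 49)), 3.0)
        cell_area = sg.cell_area_mm2
        n_foveal = (labels.labels == FOVEAL).sum()
        expected = (49 * 49 - n_foveal) * cell_area
        assert extrafoveal_area(sg, labels, 0.5) == pytest.approx(expected)
        assert area_in_regions(sg, labels, 0.5, regions=[FOVEAL]) == pytest.approx(
            n_foveal * cell_area
        )

    def test_geometry_mismatch_rejected(self):
        labels = etdrs_labels((49, 49), 3.0)
        with pytest.raises(ValueError):
            region_means(StandardGrid(np.zeros((21, 21)), 3.0), labels)
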