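"""Fishnet geometry, ERI aggregation, grade classification and transitions."""

import numpy as np
import pytest
from shapely.geometry import Polygon, box

from ecosec import (
    GradeScheme,
    build_fishnet,
    classify_grades,
    compute_eri,
    grade_area_proportions,
    grade_transition_matrix,
    jenks_breaks,
)
from ecosec.grid import RiskGrid
from ecosec.raster import LandUseRaster

KM = 1000.0


class TestBuildFishnet:
    def test_exact_tiling_square(self):
        net = build_fishnet(box(0, 0, 30 * KM, 30 * KM), cell_km=10)
        assert len(net) == 9
        np.testing.assert_allclose(net.area, (10 * KM) ** 2)

    def test_partial_cells_clipped_by_hand_geometry(self):
        """25x25 km square: corner cell 25 km2, edge cells 50 km2."""
        net = build_fishnet(box(0, 0, 25 * KM, 25 * KM), cell_km=10)
        assert len(net) == 9
        areas_km2 = sorted(net.area / 1e6)
        assert areas_km2 == pytest.approx([25, 50, 50, 50, 50, 100, 100, 100, 100])

    def test_invalid_cell_size_rejected(self):
        with pytest.raises(ValueError, match="cell_km"):
            build_fishnet(box(0, 0, KM, KM), cell_km=0)

    def test_invalid_geometry_rejected(self):
        bowtie = Polygon([(0, 0), (1, 1), (1, 0), (0, 1)])
        with pytest.raises(ValueError):
            build_fishnet(bowtie, cell_km=1)

    @pytest.mark.parametrize("cell_km", [3.0, 7.0, 10.0])
    def test_clipped_areas_conserve_boundary_area(self, cell_km):
        """Total clipped cell area equals the polygon area within 0.1%."""
        poly = Polygon([(0, 0), (28 * KM, 4 * KM), (25 * KM, 27 * KM),
                        (3 * KM, 22 * KM)])
        net = build_fishnet(poly, cell_km=cell_km, min_cover_frac=0.0)
        assert net.area.sum() == pytest.approx(poly.area, rel=1e-3)


class TestComputeEri:
    def _uniform_raster(self, code, n=20, cell=KM):
        return LandUseRaster(np.full((n, n), code, dtype=np.int64), cell_size=cell)

    def test_single_class_cell_gets_that_class_loss(self):
        net = build_fishnet(box(0, 0, 20 * KM, 20 * KM), cell_km=10)
        rg = compute_eri(net, self._uniform_raster(1), {1: 0.026})
        np.testing.assert_allclose(rg.eri, 0.026)

    def test_half_and_half_cell_averages_losses(self):
        """One 2-km cell over 1 km forest + 1 km rubber -> mean of R."""
        data = np.array([[1, 2]], dtype=np.int64)
        raster = LandUseRaster(data, cell_size=KM)
        net = build_fishnet(box(0, 0, 2 * KM, KM), cell_km=2)
        rg = compute_eri(net, raster, {1: 0.026, 2: 0.106})
        assert len(rg) == 1
        assert rg.eri[0] == pytest.approx(0.066)

    def test_convex_combination_bounds(self, clumped_raster):
        loss = {1: 0.026, 2: 0.106, 3: 0.217}
        raster = LandUseRaster(clumped_raster.data, cell_size=100.0)
        net = build_fishnet(box(0, 0, 3200, 3200), cell_km=0.8)
        rg = compute_eri(net, raster, loss)
        assert (rg.eri >= min(loss.values()) - 1e-12).all()
        assert (rg.eri <= max(loss.values()) + 1e-12).all()

    def test_missing_loss_value_rejected(self):
        net = build_fishnet(box(0, 0, 20 * KM, 20 * KM), cell_km=10)
        with pytest.raises(ValueError, match="loss"):
            compute_eri(net, self._uniform_raster(1), {2: 0.1})

    def test_area_weighted_mean_eri_is_cell_size_invariant(self, clumped_raster):
        """Halving the cell size leaves the area-weighted mean unchanged."""
        loss = {1: 0.026, 2: 0.106, 3: 0.217}
        raster = LandUseRaster(clumped_raster.data, cell_size=100.0)
        bound = box(0, 0, 3200, 3200)
        coarse = compute_eri(build_fishnet(bound, 0.8), raster, loss)
        fine = compute_eri(build_fishnet(bound, 0.4), raster, loss)

        # full cells contain equal raster-cell counts, so the cell-count-
        # weighted mean is the mean over raster cells in both tilings
        assert coarse.eri.mean() == pytest.approx(fine.eri.mean(), abs=1e-9)


class TestClassifyGrades:
    @pytest.mark.parametrize(
        "value,grade", [(0.041, 1), (0.045, 2), (0.05, 3), (0.058, 4), (0.2, 5)]
    )
    def test_interval_membership(self, value, grade):
        assert classify_grades([value])[0] == grade

    def test_breakpoint_value_falls_upward(self):
        assert classify_grades([0.042])[0] == 2
        assert classify_grades([0.06])[0] == 5

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_grades([1.5])
        with pytest.raises(ValueError):
            classify_grades([-0.1])
        with pytest.raises(ValueError):
            classify_grades([np.nan])

    def test_jenks_recovers_separated_clusters(self):
        """Exhaustive DP Jenks isolates five well-separated value clusters."""
        values = [1, 1, 1, 5, 5, 5, 9, 9, 9, 13, 13, 13, 17, 17, 17]
        scheme = jenks_breaks(values, n_classes=5)
        grades = classify_grades(np.array(values) / 20.0,
                                 GradeScheme(tuple(np.array(scheme.breakpoints) / 20.0),
                                             upper=1.0, provenance="jenks"))
        # each cluster lands in its own grade, in order
        assert list(grades) == [1] * 3 + [2] * 3 + [3] * 3 + [4] * 3 + [5] * 3

    def test_grade_scheme_validation(self):
        with pytest.raises(ValueError):
            GradeScheme((0.042, 0.040, 0.056, 0.06))


class TestGradeAreas:
    def _grid(self, grades, areas_km2):
        n = len(grades)
        from ecosec.grid import Fishnet

        net = Fishnet(cell_size=10 * KM, origin=(0, 0),
                      rows=np.arange(n), cols=np.zeros(n, dtype=int),
                      area=np.asarray(areas_km2, dtype=float) * 1e6,
                      centers=np.column_stack([np.zeros(n), np.arange(n)]))
        return RiskGrid(net, np.full(n, 0.05), np.asarray(grades))

    def test_all_one_grade(self):
        props = grade_area_proportions([1, 1, 1], [1.0, 1.0, 1.0])
        assert props["I"] == pytest.approx(100.0)
        assert props.sum() == pytest.approx(100.0, abs=1e-6)

    def test_equal_cells_split(self):
        props = grade_area_proportions([1] * 3 + [2] * 3 + [5] * 3, [1.0] * 9)
        assert props["I"] == pytest.approx(100 / 3)
        assert props["III"] == 0.0
        assert props["V"] == pytest.approx(100 / 3)

    def test_clipped_areas_weight_proportions(self):
        """A half-clipped cell counts half as much as a full one."""
        props = grade_area_proportions([1, 2], [100.0, 50.0])
        assert props["I"] == pytest.approx(200 / 3)
        assert props["II"] == pytest.approx(100 / 3)

    def test_transition_identity_is_diagonal(self):
        g = self._grid([1, 2, 3, 4, 5], [100] * 5)
        mat = grade_transition_matrix(g, g)
        assert np.allclose(np.diag(mat.to_numpy()), 100.0)
        assert mat.to_numpy().sum() == pytest.approx(500.0)

    def test_single_cell_jump_appears_off_diagonal(self):
        a = self._grid([1], [100.0])
        b = self._grid([5], [100.0])
        mat = grade_transition_matrix(a, b)
        assert mat.loc["I", "V"] == pytest.approx(100.0)
        assert mat.to_numpy().sum() == pytest.approx(100.0)

    def test_matrix_equals_brute_force_tally_and_marginals(self):
        rng = np.random.default_rng(5)
        ga = rng.integers(1, 6, size=20)
        gb = rng.integers(1, 6, size=20)
        areas = rng.uniform(50, 100, size=20)
        A, B = self._grid(ga, areas), self._grid(gb, areas)
        mat = grade_transition_matrix(A, B).to_numpy()
        brute = np.zeros((5, 5))
        for x, y, a in zip(ga, gb, areas):
            brute[x - 1, y - 1] += a
        np.testing.assert_allclose(mat, brute)
        # marginals match the grade-area tables exactly
        total = areas.sum()
        np.testing.assert_allclose(
            mat.sum(axis=1) / total * 100, grade_area_proportions(ga, areas)
        )
        np.testing.assert_allclose(
            mat.sum(axis=0) / total * 100, grade_area_proportions(gb, areas)
        )

    def test_mismatched_fishnets_rejected(self):
        a = self._grid([1, 2], [100, 100])
        b = self._grid([1, 2, 3], [100, 100, 100])
        with pytest.raises(ValueError, match="fishnet"):
            grade_transition_matrix(a, b)
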