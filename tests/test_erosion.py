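"""Erosion geometry, DEM differencing, and the N-mobilization budget chain."""

import numpy as np
import pytest
from shapely.geometry import Polygon

from thawnitro.erosion import (
    ErosionScene,
    annual_volume_per_area,
    dem_volume,
    emission_budget,
    n_mobilization,
    read_ascii_grid,
    read_polylines_csv,
    transect_retreat,
    write_ascii_grid,
    write_polylines_csv,
)
from thawnitro.synthetic import sim_dem_pair


class TestAsciiGridRoundtrip:
    def test_roundtrip_with_nodata(self, tmp_path):
        arr = np.arange(12, dtype=float).reshape(3, 4)
        arr[0, 0] = np.nan
        path = tmp_path / "dem.asc"
        write_ascii_grid(path, arr, xllcorner=100.0, yllcorner=200.0, cellsize=2.0)
        back, header = read_ascii_grid(path)
        assert header["ncols"] == 4 and header["nrows"] == 3
        assert header["cellsize"] == 2.0
        assert np.isnan(back[0, 0])
        np.testing.assert_allclose(back[1:], arr[1:])

    def test_polyline_roundtrip(self, tmp_path):
        lines = {2012.0: np.array([[0.0, 1.0], [5.0, 2.0]]),
                 2019.0: np.array([[0.0, 8.0], [5.0, 9.0]])}
        path = tmp_path / "cliff.csv"
        write_polylines_csv(path, lines)
        back = read_polylines_csv(path)
        for d in lines:
            np.testing.assert_allclose(back[d], lines[d])


class TestTransectRetreat:
    def test_identical_boundaries_zero_rate(self):
        scene = sim_dem_pair(40, 80, 5.0, 20.0, retreat=0.0)
        stats = transect_retreat(scene, spacing=20.0)
        assert stats.median == 0.0 and stats.q25 == 0.0 and stats.q75 == 0.0

    def test_parallel_lines_exact_rate(self):
        # straight parallel lines offset 25.9 m over 7 years: 3.7 m/yr everywhere
        line0 = np.array([[0.0, 50.0], [400.0, 50.0]])
        line1 = np.array([[0.0, 75.9], [400.0, 75.9]])
        scene = ErosionScene(
            dem_old=np.zeros((2, 2)), dem_new=np.zeros((2, 2)), cell_size=1.0,
            shoreline=np.array([[0.0, 0.0], [400.0, 0.0]]),
            cliff_boundaries={2012.0: line0, 2019.0: line1},
            epoch_years=7.0,
        )
        stats = transect_retreat(scene, spacing=10.0)
        np.testing.assert_allclose(stats.per_transect_rates, 3.7)
        assert stats.median == pytest.approx(3.7)

    def test_spacing_invariance_for_straight_cliff(self):
        scene = sim_dem_pair(50, 100, 4.0, 20.0, retreat=10.0, epoch_years=1.0)
        for spacing in (5.0, 17.0, 40.0):
            assert transect_retreat(scene, spacing=spacing).median == pytest.approx(10.0)

    def test_generator_roundtrip(self):
        scene = sim_dem_pair(50, 100, 4.0, 20.0, retreat=10.0, epoch_years=2.0)
        stats = transect_retreat(scene, spacing=10.0)
        assert stats.median == pytest.approx(10.0 / 2.0)

    def test_no_intersection_errors(self):
        scene = ErosionScene(
            dem_old=np.zeros((2, 2)), dem_new=np.zeros((2, 2)), cell_size=1.0,
            shoreline=np.array([[0.0, 0.0], [10.0, 0.0]]),
            # cliff lines far off to the side: no perpendicular transect can hit them
            cliff_boundaries={0.0: np.array([[500.0, 5.0], [510.0, 5.0]]),
                              1.0: np.array([[500.0, 8.0], [510.0, 8.0]])},
            epoch_years=1.0,
        )
        with pytest.raises(ValueError):
            transect_retreat(scene, spacing=5.0)


class TestDemVolume:
    def test_identical_grids(self):
        g = np.random.default_rng(0).random((10, 10))
        assert dem_volume(g, g.copy(), 2.0) == 0.0

    def test_uniform_drop(self):
        old = np.ones((10, 10))
        new = np.zeros((10, 10))
        assert dem_volume(old, new, 2.0) == pytest.approx(100 * 1 * 4.0)

    def test_positive_only_convention(self):
        old = np.zeros((5, 5))
        new = np.ones((5, 5))  # uplift everywhere: no erosion volume
        assert dem_volume(old, new, 1.0) == 0.0

    def test_nodata_skipped(self):
        old = np.ones((4, 4))
        new = np.zeros((4, 4))
        old[0, 0] = np.nan
        assert dem_volume(old, new, 1.0) == pytest.approx(15.0)

    def test_generator_volume_within_one_row(self):
        scene = sim_dem_pair(50, 100, cell_size=4.0, cliff_height=20.0, retreat=10.0)
        vol = dem_volume(scene.dem_old, scene.dem_new, scene.cell_size)
        one_row = scene.cell_size * scene.section_length * 20.0
        assert abs(vol - scene.true_volume) <= one_row

    def test_polygon_mask(self):
        old = np.ones((10, 10))
        new = np.zeros((10, 10))
        # left half of the 10x10 unit grid
        mask = Polygon([(0, 0), (5, 0), (5, 10), (0, 10)])
        assert dem_volume(old, new, 1.0, mask=mask) == pytest.approx(50.0)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            dem_volume(np.zeros((3, 3)), np.zeros((4, 4)), 1.0)


class TestBudgetChain:
    def test_annual_volume_printed_inputs(self):
        # 223502 m3 over 7 yr, normalized by 3.7 m/yr x 1700 m footprint
        assert annual_volume_per_area(223502, 7, 3.7, 1700) == pytest.approx(5.076, abs=1e-3)

    def test_volume_zero(self):
        assert annual_volume_per_area(0, 7, 3.7, 1700) == 0.0

    def test_epoch_linearity(self):
        one = annual_volume_per_area(1000, 1, 2, 100)
        assert annual_volume_per_area(1000, 2, 2, 100) == pytest.approx(one / 2)

    def test_n_mobilization_hand_chain(self):
        b = n_mobilization(5.076, ice_fraction=0.82, bulk_density=1220.0,
                           total_n_frac=0.0016, mineral_n_content=35.3)
        assert b.total_n_release == pytest.approx(1.78, abs=0.01)
        assert b.mineral_n_release == pytest.approx(39.4, abs=0.1)

    def test_zero_volume_zero_release(self):
        b = n_mobilization(0.0)
        assert b.total_n_release == 0.0 and b.mineral_n_release == 0.0

    def test_mineral_total_unit_identity(self):
        # mineral content equal to total fraction (in mg/kg) makes g = 1000 x kg
        b = n_mobilization(5.0, total_n_frac=0.0016, mineral_n_content=0.0016 * 1e6)
        assert b.mineral_n_release == pytest.approx(1000.0 * b.total_n_release)

    def test_linear_in_volume(self):
        b1 = n_mobilization(2.0)
        b2 = n_mobilization(4.0)
        assert b2.total_n_release == pytest.approx(2 * b1.total_n_release)

    def test_ice_fraction_validation(self):
        with pytest.raises(ValueError):
            n_mobilization(5.0, ice_fraction=1.0)


class TestEmissionBudget:
    def test_seasonal_loss(self):
        e = emission_budget(548.0, 100.0)
        assert e.seasonal_loss == pytest.approx(54.8)

    def test_emission_factor_and_fold(self):
        e = emission_budget(548.0, 100.0, mineral_n_release=39.0)
        assert e.emission_factor == pytest.approx(54.8 / 39000 * 100)
        assert round(e.emission_factor, 2) == 0.14
        assert round(e.fold_below_ipcc) == 7

    def test_zero_flux(self):
        e = emission_budget(0.0, 100.0, mineral_n_release=39.0)
        assert e.seasonal_loss == 0.0 and e.emission_factor == 0.0
        assert e.fold_below_ipcc is None

    def test_zero_mineral_release_errors(self):
        with pytest.raises(ValueError):
            emission_budget(548.0, 100.0, mineral_n_release=0.0)
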