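"""Spatial calibration, surrogate weights and conservative allocation."""
import numpy as np
import pytest

from nutrigrid.accounting import ProvinceSectorTotal
from nutrigrid.grids import Affine, GridAlignmentError, Raster, require_aligned
from nutrigrid.spatial import (
    SECTOR_LANDUSE,
    aggregate_to_provinces,
    allocate,
    build_weights,
    calibrate_population,
    clay_coefficient,
    landuse_mask,
    slope_coefficient,
    slope_from_dem,
)

XF = Affine.from_origin(0.0, 100.0, 1.0, 1.0)


def raster(values, nodata=-9999.0):
    return Raster(np.asarray(values, dtype=np.float64), XF, nodata=nodata)


def iraster(values, nodata=-1):
    return Raster(np.asarray(values, dtype=np.int64), XF, nodata=nodata)


class TestCalibratePopulation:
    def test_correction_factor_scales_cells(self):
        # Province reference sum 1000, statistics 2000: every cell doubles.
        ref = raster([[10.0, 990.0]])
        prov = iraster([[1, 1]])
        grid = calibrate_population(ref, prov, {1: 2000.0})
        assert grid.calibrated.values[0, 0] == pytest.approx(20.0, rel=1e-12)
        assert grid.province_factors[1] == pytest.approx(2.0)

    def test_identity_when_statistics_match_reference(self):
        ref = raster([[10.0, 20.0], [30.0, 40.0]])
        prov = iraster([[1, 1], [1, 1]])
        grid = calibrate_population(ref, prov, {1: 100.0})
        np.testing.assert_allclose(grid.calibrated.values, ref.values)

    def test_per_province_sums_match_statistics(self):
        rng = np.random.default_rng(0)
        ref = raster(rng.uniform(0, 50, (8, 8)))
        prov = iraster(rng.integers(1, 4, (8, 8)))
        sta = {1: 1234.5, 2: 67.8, 3: 9999.0}
        grid = calibrate_population(ref, prov, sta)
        for p, target in sta.items():
            total = grid.calibrated.values[prov.values == p].sum()
            assert total == pytest.approx(target, rel=1e-9)

    def test_zero_reference_with_positive_statistics_errors(self):
        ref = raster([[0.0, 0.0]])
        prov = iraster([[1, 1]])
        with pytest.raises(ValueError, match="zero field"):
            calibrate_population(ref, prov, {1: 100.0})


class TestLanduseMask:
    LU = [[1, 2, 3], [4, 5, 4]]

    @pytest.mark.parametrize(
        "sector,expected",
        [
            ("urban", [[1, 0, 0], [0, 0, 0]]),
            ("rural", [[0, 1, 0], [0, 0, 0]]),
            ("industrial", [[1, 0, 1], [0, 0, 0]]),
            ("crop", [[0, 0, 0], [1, 0, 1]]),
            ("livestock", [[0, 0, 0], [1, 0, 1]]),
        ],
    )
    def test_sector_eligible_classes(self, sector, expected):
        mask = landuse_mask(iraster(self.LU), sector)
        np.testing.assert_array_equal(mask.values, np.asarray(expected, dtype=float))

    def test_unknown_category_code_errors(self):
        with pytest.raises(ValueError, match="unknown land-use"):
            landuse_mask(iraster([[1, 9]]), "urban")

    def test_unknown_sector_errors(self):
        with pytest.raises(KeyError, match="unknown sector"):
            landuse_mask(iraster(self.LU), "aquaculture")

    def test_nodata_propagates(self):
        mask = landuse_mask(iraster([[1, -1]]), "urban")
        assert mask.values[0, 1] == mask.nodata


class TestSlope:
    def test_flat_field_zero_slope(self):
        dem = raster(np.full((6, 6), 123.0))
        np.testing.assert_allclose(slope_from_dem(dem).values, 0.0, atol=1e-12)

    def test_inclined_plane_percent_slope(self):
        # z = 0.1 m per metre of x: a 10 % slope everywhere on the interior.
        cols = np.arange(8, dtype=float)
        dem = raster(np.tile(0.1 * cols, (8, 1)))
        slope = slope_from_dem(dem).values
        np.testing.assert_allclose(slope[1:-1, 1:-1], 10.0, rtol=1e-12)

    def test_invariant_under_constant_offset(self):
        rng = np.random.default_rng(1)
        z = rng.uniform(0, 100, (7, 7))
        s1 = slope_from_dem(raster(z)).values
        s2 = slope_from_dem(raster(z + 500.0)).values
        np.testing.assert_allclose(s1, s2, atol=1e-9)

    def test_degenerate_grid_errors(self):
        with pytest.raises(ValueError, match="too small"):
            slope_from_dem(raster([[1.0]]))


class TestCoefficientGrades:
    @pytest.mark.parametrize(
        "slope,coef",
        [(0.0, 0.10), (7.999, 0.10), (8.0, 0.20), (14.0, 0.20),
         (15.0, 0.35), (20.0, 0.35), (24.999, 0.35), (25.0, 0.50),
         (30.0, 0.50), (500.0, 0.50)],
    )
    def test_slope_grades(self, slope, coef):
        assert slope_coefficient(slope) == coef

    @pytest.mark.parametrize(
        "clay,coef",
        [(0.0, 0.75), (10.0, 0.75), (17.999, 0.75), (18.0, 0.50),
         (30.0, 0.50), (35.0, 0.25), (45.0, 0.25), (60.0, 0.10), (100.0, 0.10)],
    )
    def test_clay_grades(self, clay, coef):
        assert clay_coefficient(clay) == coef

    def test_negative_slope_errors(self):
        with pytest.raises(ValueError, match="slope"):
            slope_coefficient(-1.0)

    def test_clay_out_of_range_errors(self):
        with pytest.raises(ValueError, match="clay"):
            clay_coefficient(101.0)

    def test_vectorized_lookup_matches_scalar(self):
        vals = np.array([[3.0, 12.0], [19.0, 40.0]])
        out = slope_coefficient(vals)
        np.testing.assert_array_equal(out, [[0.10, 0.20], [0.35, 0.50]])


class TestBuildWeights:
    def test_population_proportional_shares(self):
        lu = iraster([[1, 1, 5]])
        prov = iraster([[1, 1, 1]])
        ref = raster([[30.0, 70.0, 999.0]])
        pop = calibrate_population(ref, prov, {1: 1099.0})
        w = build_weights("urban", landuse_mask(lu, "urban"),
                          population=pop, province_ids=prov)
        np.testing.assert_allclose(w.weights.values[0, :2], [0.3, 0.7], rtol=1e-12)
        assert w.weights.values[0, 2] == 0.0
        assert w.normalization[1] == "proxy"

    def test_terrain_surrogate_shares(self):
        # slope coefs 0.10 and 0.50, clay coefs both 0.50: shares 1/6, 5/6.
        lu = iraster([[4, 4]])
        prov = iraster([[1, 1]])
        slope_coef = raster([[0.10, 0.50]])
        clay_coef = raster([[0.50, 0.50]])
        w = build_weights("crop", landuse_mask(lu, "crop"),
                          slope_coef=slope_coef, clay_coef=clay_coef,
                          province_ids=prov)
        np.testing.assert_allclose(w.weights.values[0], [1 / 6, 5 / 6], rtol=1e-12)

    def test_fallback_uniform_over_eligible_cells(self):
        lu = iraster([[1, 1, 5]])
        prov = iraster([[1, 1, 1]])
        ref = raster([[0.0, 0.0, 10.0]])  # no population on urban land
        pop = calibrate_population(ref, prov, {1: 10.0})
        w = build_weights("urban", landuse_mask(lu, "urban"),
                          population=pop, province_ids=prov)
        np.testing.assert_allclose(w.weights.values[0], [0.5, 0.5, 0.0])
        assert w.normalization[1] == "uniform_eligible"

    def test_fallback_uniform_over_province(self):
        lu = iraster([[5, 5]])  # no eligible land at all
        prov = iraster([[1, 1]])
        ref = raster([[1.0, 3.0]])
        pop = calibrate_population(ref, prov, {1: 4.0})
        w = build_weights("urban", landuse_mask(lu, "urban"),
                          population=pop, province_ids=prov)
        np.testing.assert_allclose(w.weights.values[0], [0.5, 0.5])
        assert w.normalization[1] == "uniform_province"

    def test_weights_are_probability_distribution_per_province(self, scenario):
        from nutrigrid.spatial import slope_from_dem

        pop = calibrate_population(
            scenario.reference_pop, scenario.province_ids, scenario.sta_pop(2020)
        )
        slope = slope_from_dem(scenario.dem)
        slope_coef = slope.with_values(slope_coefficient(slope.filled(0.0)))
        clay_coef = scenario.clay.with_values(
            clay_coefficient(scenario.clay.filled(0.0)))
        for sector in SECTOR_LANDUSE:
            w = build_weights(
                sector, landuse_mask(scenario.landuse, sector),
                population=pop, slope_coef=slope_coef, clay_coef=clay_coef,
                province_ids=scenario.province_ids,
            )
            vals = w.weights.filled(0.0)
            assert (vals >= 0).all()
            for p in scenario.provinces:
                cells = scenario.province_ids.values == p
                assert vals[cells].sum() == pytest.approx(1.0, abs=1e-9)


def simple_setup():
    prov = iraster([[1, 1, 2], [1, 2, 2]])
    lu = iraster([[1, 1, 1], [1, 1, 1]])
    ref = raster([[30.0, 70.0, 10.0], [0.0, 40.0, 50.0]])
    pop = calibrate_population(ref, prov, {1: 100.0, 2: 100.0})
    w = build_weights("urban", landuse_mask(lu, "urban"),
                      population=pop, province_ids=prov)
    return prov, w


def totals(masses, sector="urban"):
    return [
        ProvinceSectorTotal(p, 2020, "TN", sector, m) for p, m in masses.items()
    ]


class TestAllocate:
    def test_cells_receive_weighted_share(self):
        prov, w = simple_setup()
        inv = allocate(totals({1: 100.0, 2: 0.0}), w, prov)
        vals = inv.data[("urban", "TN")].values
        np.testing.assert_allclose(vals[0, :2], [30.0, 70.0], rtol=1e-12)
        assert vals[1, 0] == 0.0  # zero-population cell
        np.testing.assert_allclose(vals[:, 2], 0.0)

    def test_zero_total_zero_raster(self):
        prov, w = simple_setup()
        inv = allocate(totals({1: 0.0, 2: 0.0}), w, prov)
        np.testing.assert_allclose(inv.data[("urban", "TN")].values, 0.0)

    def test_national_conservation(self):
        prov, w = simple_setup()
        inv = allocate(totals({1: 123.4, 2: 56.7}), w, prov)
        assert inv.data[("urban", "TN")].values.sum() == pytest.approx(
            180.1, rel=1e-12
        )

    def test_homogeneous_degree_one(self):
        prov, w = simple_setup()
        base = allocate(totals({1: 10.0, 2: 5.0}), w, prov)
        doubled = allocate(totals({1: 20.0, 2: 5.0}), w, prov)
        b = base.data[("urban", "TN")].values
        d = doubled.data[("urban", "TN")].values
        p1 = prov.values == 1
        np.testing.assert_allclose(d[p1], 2 * b[p1], rtol=1e-12)
        np.testing.assert_allclose(d[~p1], b[~p1], rtol=1e-12)

    def test_missing_province_errors(self):
        prov, w = simple_setup()
        with pytest.raises(ValueError, match="absent from the grid"):
            allocate(totals({1: 1.0, 3: 1.0}), w, prov)

    def test_matches_brute_force_loop(self):
        # Bit-for-bit agreement with a per-cell loop on a 10×10 grid.
        rng = np.random.default_rng(5)
        prov = iraster(rng.integers(1, 4, (10, 10)))
        lu = iraster(rng.choice([1, 2, 4, 5], (10, 10)))
        ref = raster(rng.uniform(0, 100, (10, 10)))
        pop = calibrate_population(ref, prov, {1: 50.0, 2: 60.0, 3: 70.0})
        w = build_weights("urban", landuse_mask(lu, "urban"),
                          population=pop, province_ids=prov)
        masses = {1: 11.0, 2: 22.0, 3: 33.0}
        inv = allocate(totals(masses), w, prov)
        expected = np.zeros((10, 10))
        for r in range(10):
            for c in range(10):
                p = int(prov.values[r, c])
                expected[r, c] = masses[p] * w.weights.values[r, c]
        np.testing.assert_array_equal(inv.data[("urban", "TN")].values, expected)


class TestAggregate:
    def test_round_trip_identity(self):
        prov, w = simple_setup()
        masses = {1: 42.0, 2: 17.5}
        inv = allocate(totals(masses), w, prov)
        back = aggregate_to_provinces(inv, prov)
        got = {t.province_id: t.mass for t in back}
        for p, m in masses.items():
            assert got[p] == pytest.approx(m, rel=1e-12)

    def test_single_province_national_total(self):
        prov = iraster([[1, 1]])
        lu = iraster([[1, 1]])
        ref = raster([[2.0, 3.0]])
        pop = calibrate_population(ref, prov, {1: 5.0})
        w = build_weights("urban", landuse_mask(lu, "urban"),
                          population=pop, province_ids=prov)
        inv = allocate(totals({1: 9.0}), w, prov)
        back = aggregate_to_provinces(inv, prov)
        assert sum(t.mass for t in back) == pytest.approx(9.0, rel=1e-12)

    def test_label_permutation_preserves_national_sum(self):
        prov, w = simple_setup()
        inv = allocate(totals({1: 10.0, 2: 30.0}), w, prov)
        national = sum(t.mass for t in aggregate_to_provinces(inv, prov))
        permuted = prov.with_values(np.where(prov.values == 1, 2, 1))
        national_permuted = sum(
            t.mass for t in aggregate_to_provinces(inv, permuted)
        )
        assert national_permuted == pytest.approx(national, rel=1e-12)


class TestAlignment:
    def test_mismatched_grids_rejected(self):
        a = raster(np.zeros((2, 2)))
        b = Raster(np.zeros((2, 2)), Affine.from_origin(5.0, 5.0, 1.0, 1.0))
        with pytest.raises(GridAlignmentError, match="grid mismatch"):
            require_aligned(a, b)
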