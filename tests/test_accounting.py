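"""Unit and property tests for the sector accounting equations."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nutrigrid.accounting import (
    SECTORS,
    SPECIES,
    CropParams,
    IndustrySeries,
    LivestockParams,
    ParameterError,
    ProvinceSectorTotal,
    RuralParams,
    SpeciesParams,
    UrbanParams,
    crop_discharge,
    industrial_discharge,
    livestock_discharge,
    rural_discharge,
    total_discharge,
    urban_discharge,
)

fractions = st.floats(0.0, 1.0, allow_nan=False)
positives = st.floats(0.0, 1e7, allow_nan=False)


def make_urban(**kw):
    base = dict(u_pop=1000, um_water=100, ur_direct=0.0, ur_treat=0.8,
                ur_reuse=0.25, uc_direct=30.0, uc_treat=15.0)
    base.update(kw)
    return UrbanParams(**base)


def make_rural(**kw):
    base = dict(r_pop=1000, rr_dry=0.4, rr_flu=0.6, rm_dry=1.0, rm_flu=3.0,
                rm_direct=0.5, rm_treat=0.5, rm_removal=0.6)
    base.update(kw)
    return RuralParams(**base)


class TestUrban:
    def test_treated_pathway_hand_example(self):
        # 1000 people at 100 L/day, 80% treated, 25% reused, 15 mg/L effluent.
        result = urban_discharge(make_urban(), "TN")
        assert result.total == pytest.approx(0.3285, rel=1e-12)
        assert result.components["direct"] == 0.0

    def test_no_pathways_no_discharge(self):
        p = make_urban(ur_direct=0.0, ur_treat=0.0)
        assert urban_discharge(p, "TN").total == 0.0

    def test_full_reuse_eliminates_treated_discharge(self):
        p = make_urban(ur_reuse=1.0)
        assert urban_discharge(p, "TN").total == 0.0

    @pytest.mark.parametrize(
        "field,value",
        [("u_pop", -1.0), ("ur_treat", 1.5), ("ur_reuse", -0.1)],
    )
    def test_validation_names_offending_field(self, field, value):
        with pytest.raises(ParameterError, match=field):
            make_urban(**{field: value})

    def test_direct_plus_treated_share_capped(self):
        with pytest.raises(ParameterError, match="ur_direct \\+ ur_treat"):
            make_urban(ur_direct=0.5, ur_treat=0.8)

    def test_monotone_decreasing_in_reuse(self):
        masses = [
            urban_discharge(make_urban(ur_reuse=r), "TN").total
            for r in np.linspace(0, 1, 7)
        ]
        assert all(a > b for a, b in zip(masses, masses[1:]))

    @given(pop=st.floats(1, 1e7), reuse=st.floats(0, 0.99))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_population(self, pop, reuse):
        lo = urban_discharge(make_urban(u_pop=pop, ur_reuse=reuse), "TN").total
        hi = urban_discharge(make_urban(u_pop=pop * 2, ur_reuse=reuse), "TN").total
        assert hi > lo


class TestRural:
    def test_hand_example_with_components(self):
        result = rural_discharge(make_rural(), "TN")
        assert result.components["direct"] == pytest.approx(1.100, rel=1e-12)
        assert result.components["treated"] == pytest.approx(0.440, rel=1e-12)
        assert result.total == pytest.approx(1.540, rel=1e-12)

    def test_perfect_treatment_no_discharge(self):
        p = make_rural(rm_direct=0.0, rm_removal=1.0)
        assert rural_discharge(p, "TN").total == 0.0

    def test_zero_generation_coefficient(self):
        p = make_rural(rr_dry=1.0, rr_flu=0.0, rm_dry=0.0)
        assert rural_discharge(p, "TN").total == 0.0

    def test_toilet_shares_must_sum_to_one(self):
        with pytest.raises(ParameterError, match="rr_dry \\+ rr_flu"):
            make_rural(rr_dry=0.5, rr_flu=0.6)

    def test_monotone_decreasing_in_removal(self):
        masses = [
            rural_discharge(make_rural(rm_removal=r), "TN").total
            for r in np.linspace(0, 1, 6)
        ]
        assert all(a > b for a, b in zip(masses, masses[1:]))


class TestGenerationBound:
    """All-direct, zero-treatment parameters give the raw upper bound and
    any intermediate parameterization stays within it."""

    @given(
        treat=fractions, reuse=fractions, data=st.data()
    )
    @settings(max_examples=50, deadline=None)
    def test_urban_between_zero_and_bound(self, treat, reuse, data):
        direct = data.draw(st.floats(0.0, 1.0 - treat))
        bound = urban_discharge(
            make_urban(ur_direct=1.0, ur_treat=0.0, uc_direct=30.0), "TN"
        ).total
        p = make_urban(ur_direct=direct, ur_treat=treat, ur_reuse=reuse,
                       uc_direct=30.0, uc_treat=30.0)
        mass = urban_discharge(p, "TN").total
        assert 0.0 <= mass <= bound + 1e-12


class TestIndustrial:
    def make_series(self, discharge, years=None, gdp=None):
        years = years or sorted(
            set(discharge) | set(gdp or {})
        )
        gdp = gdp or {y: 100.0 * 1.07 ** (y - years[0]) for y in years}
        return IndustrySeries(years=years, gdp=gdp, discharge={"TN": discharge})

    def test_observed_year_pass_through(self):
        s = self.make_series({2000: 12.0, 2005: 20.0})
        est = industrial_discharge(s, 2000, "TN")
        assert est.mass == 12.0 and est.flag == "observed"

    def test_two_points_on_loglog_line(self):
        # discharge = 2 * gdp^0.5 at the two observed years; the gap-fill
        # must land exactly on that power law.
        gdp = {2000: 100.0, 2001: 150.0, 2002: 225.0}
        disch = {2000: 2 * 100.0**0.5, 2002: 2 * 225.0**0.5}
        s = IndustrySeries(years=[2000, 2001, 2002], gdp=gdp,
                           discharge={"TN": disch})
        est = industrial_discharge(s, 2001, "TN")
        assert est.flag == "imputed"
        assert est.mass == pytest.approx(2 * 150.0**0.5, rel=1e-9)

    def test_single_observation_constant_fill(self):
        s = self.make_series({2000: 5.0}, years=[2000, 2001],
                             gdp={2000: 10.0, 2001: 20.0})
        est = industrial_discharge(s, 2001, "TN")
        assert est.mass == 5.0 and est.flag == "imputed"

    def test_no_observations_errors(self):
        s = self.make_series({2000: 5.0})
        with pytest.raises(ParameterError, match="no observed"):
            industrial_discharge(s, 2000, "TP")

    def test_missing_gdp_errors(self):
        s = self.make_series({2000: 5.0, 2002: 7.0},
                             gdp={2000: 10.0, 2002: 30.0}, years=[2000, 2002])
        with pytest.raises(ParameterError, match="gdp missing"):
            industrial_discharge(s, 2001, "TN")

    def test_pass_through_on_random_series(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            years = sorted(rng.choice(np.arange(1990, 2021), 6, replace=False))
            gdp = {int(y): float(rng.uniform(10, 1e4)) for y in years}
            disch = {int(y): float(rng.uniform(0, 100)) for y in years[:4]}
            s = IndustrySeries(years=years, gdp=gdp, discharge={"TN": disch})
            for y, v in disch.items():
                assert industrial_discharge(s, y, "TN") == (v, "observed")


class TestCrop:
    def test_fertilizer_scaled_hand_example(self):
        p = CropParams(f_area=100, fm_2017=2.0, f_fertilizer_y=150,
                       f_fertilizer_2017=100)
        assert crop_discharge(p, "TN") == pytest.approx(0.300, rel=1e-12)

    def test_baseline_year_ratio_one(self):
        p = CropParams(f_area=100, fm_2017=2.0, f_fertilizer_y=100,
                       f_fertilizer_2017=100)
        assert crop_discharge(p, "TN") == pytest.approx(100 * 2.0 * 1e-3)

    def test_zero_area_zero_discharge(self):
        p = CropParams(f_area=0, fm_2017=2.0, f_fertilizer_y=100,
                       f_fertilizer_2017=100)
        assert crop_discharge(p, "TN") == 0.0

    def test_zero_baseline_fertilizer_errors(self):
        with pytest.raises(ParameterError, match="f_fertilizer_2017"):
            CropParams(f_area=1, fm_2017=1.0, f_fertilizer_y=1,
                       f_fertilizer_2017=0)

    def test_linear_in_sown_area(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            area = rng.uniform(1, 1e6)
            kw = dict(fm_2017=rng.uniform(0.1, 3), f_fertilizer_y=rng.uniform(1, 200),
                      f_fertilizer_2017=100)
            one = crop_discharge(CropParams(f_area=area, **kw), "TN")
            three = crop_discharge(CropParams(f_area=3 * area, **kw), "TN")
            assert three == pytest.approx(3 * one, rel=1e-12)


def make_species(**kw):
    base = dict(l_num=100, lr_pst=0.0, lr_centralized=0.7, lr_free=0.3,
                lm_centralized=0.5, lm_free=0.8)
    base.update(kw)
    return SpeciesParams(**base)


class TestLivestock:
    def test_single_species_hand_example(self):
        p = LivestockParams(species={"pig": make_species()})
        result = livestock_discharge(p, "TN")
        assert result.components["centralized"] == pytest.approx(0.035, rel=1e-12)
        assert result.components["free_range"] == pytest.approx(0.024, rel=1e-12)
        assert result.total == pytest.approx(0.059, rel=1e-12)
        assert result.components["by_species:pig"] == pytest.approx(0.059, rel=1e-12)

    def test_full_pastoral_ruminants_removed(self):
        p = LivestockParams(species={
            "beef_cattle": make_species(lr_pst=1.0),
            "dairy_cow": make_species(lr_pst=1.0),
            "sheep": make_species(lr_pst=1.0),
        })
        assert livestock_discharge(p, "TN").total == 0.0

    def test_pastoral_ratio_forced_zero_for_monogastrics(self):
        p = LivestockParams(species={"pig": make_species(lr_pst=0.9)})
        assert p.species["pig"].lr_pst == 0.0

    def test_no_farming_modes_no_discharge(self):
        p = LivestockParams(
            species={"pig": make_species(lr_centralized=0.0, lr_free=0.0)}
        )
        assert livestock_discharge(p, "TN").total == 0.0

    def test_unknown_species_errors(self):
        with pytest.raises(ParameterError, match="unknown species"):
            LivestockParams(species={"goat": make_species()})

    def test_linear_in_headcount(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n = rng.uniform(1, 1e6)
            one = livestock_discharge(
                LivestockParams(species={"sheep": make_species(l_num=n)}), "TN"
            ).total
            doubled = livestock_discharge(
                LivestockParams(species={"sheep": make_species(l_num=2 * n)}), "TN"
            ).total
            assert doubled == pytest.approx(2 * one, rel=1e-12)


class TestTotal:
    def components(self, masses):
        return [
            ProvinceSectorTotal(1, 2020, "TN", s, m)
            for s, m in zip(SECTORS, masses)
        ]

    def test_sum_of_sectors(self):
        result = total_discharge(self.components([1, 2, 3, 4, 5]))
        assert result.mass == 15.0
        assert math.fsum(result.shares.values()) == pytest.approx(1.0, abs=1e-15)

    def test_all_zero(self):
        result = total_discharge(self.components([0, 0, 0, 0, 0]))
        assert result.mass == 0.0
        assert all(v == 0.0 for v in result.shares.values())

    def test_mixed_keys_rejected(self):
        comps = self.components([1, 2, 3, 4, 5])
        comps[0] = ProvinceSectorTotal(2, 2020, "TN", "urban", 1.0)
        with pytest.raises(ParameterError, match="mixed"):
            total_discharge(comps)

    def test_missing_sector_rejected(self):
        with pytest.raises(ParameterError, match="one total per sector"):
            total_discharge(self.components([1, 2, 3, 4, 5])[:4])

    def test_exact_sum_machine_precision(self):
        rng = np.random.default_rng(3)
        masses = rng.uniform(0, 1e6, 5)
        result = total_discharge(self.components(masses))
        assert result.mass == math.fsum(masses)
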