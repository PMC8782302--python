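"""Crop core: phenology, canopy, CO2 response, stress, growth bookkeeping."""

import math

import numpy as np
import pytest

from agroens.crop import (CropState, GrowthInputs, VARIANTS, co2_response,
                          daily_growth, finalize_season, intercepted_fraction,
                          layer_interception, maize_genotype, sow,
                          step_phenology, water_n_stress, wheat_genotype,
                          STAGE_GRAINFILL, STAGE_MATURE, STAGE_VEGETATIVE)


def grow_season(variant_id, params, days=220, srad=20.0, tmean=18.0,
                co2=360.0, f_water=1.0, f_n=1.0):
    """Unstressed synthetic season without a soil column."""
    variant = VARIANTS[variant_id]
    state = sow(CropState(), 1, params)
    env = GrowthInputs(srad=srad, tmean=tmean, co2=co2,
                       f_water=f_water, f_n=f_n)
    for day in range(2, days + 2):
        state = step_phenology(state, tmean, params, day)
        state, _ = daily_growth(state, variant, env, params)
        if state.stage == STAGE_MATURE:
            break
    return state


class TestPhenology:
    def test_no_accumulation_below_base_temperature(self, maize):
        state = sow(CropState(), 100, maize)
        out = step_phenology(state, maize.t_base - 1.0, maize, 101)
        assert out.tt == 0.0

    def test_flowering_day_from_constant_temperature(self):
        params = wheat_genotype(t_base=0.0, tt_flowering=900.0, tt_maturity=1800.0)
        state = sow(CropState(), 0, params)
        day = 0
        while state.stage == STAGE_VEGETATIVE:
            day += 1
            state = step_phenology(state, 15.0, params, day)
        assert day == 60  # 900 degC d / 15 degC per day

    @pytest.mark.parametrize("variant", list(VARIANTS))
    def test_warming_shortens_cycle(self, variant, wheat):
        days = []
        for dt in (0.0, 2.0, 4.0, 6.0):
            state = grow_season(variant, wheat, tmean=17.0 + dt)
            assert state.stage == STAGE_MATURE
            days.append(state.maturity_doy)
        assert all(a > b for a, b in zip(days, days[1:]))


class TestInterception:
    def test_zero_lai_intercepts_nothing(self):
        for scheme in ("big_leaf", "multilayer3", "multilayer5", "two_leaf"):
            assert intercepted_fraction(0.0, 0.6, scheme) == 0.0

    def test_big_leaf_hand_value(self):
        assert intercepted_fraction(3.0, 0.6, "big_leaf") == pytest.approx(
            1.0 - math.exp(-1.8), abs=1e-12)

    def test_multilayer_telescopes_to_big_leaf(self):
        for n, scheme in ((3, "multilayer3"), (5, "multilayer5")):
            layers = layer_interception(3.0, 0.6, n)
            assert sum(layers) == pytest.approx(
                intercepted_fraction(3.0, 0.6, "big_leaf"), abs=1e-12)

    def test_all_schemes_agree_in_total(self):
        for scheme in ("multilayer3", "multilayer5", "two_leaf"):
            assert intercepted_fraction(2.5, 0.55, scheme) == pytest.approx(
                intercepted_fraction(2.5, 0.55, "big_leaf"), abs=1e-12)


class TestCo2Response:
    def test_reference_is_unity_for_both_pathways(self):
        assert co2_response(360.0, "C3") == pytest.approx(1.0)
        assert co2_response(360.0, "C4") == pytest.approx(1.0)

    def test_c4_saturates_at_450(self):
        assert co2_response(720.0, "C4") == co2_response(450.0, "C4")
        assert co2_response(450.0, "C4") > co2_response(360.0, "C4")

    def test_c3_strictly_increasing_up_to_doubling(self):
        grid = np.linspace(360.0, 720.0, 20)
        vals = [co2_response(c, "C3") for c in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_c3_doubling_boost_calibrated(self):
        p = wheat_genotype()
        assert co2_response(720.0, "C3", p) == pytest.approx(1.0 + p.co2_boost,
                                                             rel=1e-9)


class TestStress:
    def _theta_mid(self, grid):
        hyd = grid.hydraulics
        return 0.5 * (hyd.theta_pwp + hyd.theta_fc)

    def test_full_supply_no_stress(self, adet_grid, wheat):
        state = sow(CropState(), 1, wheat)
        hyd = adet_grid.hydraulics
        fw, fn, _ = water_n_stress(state, VARIANTS["ceres_like"], wheat,
                                   hyd.theta_fc, hyd.theta_fc, hyd.theta_pwp,
                                   adet_grid.thickness_mm, adet_grid.z_top,
                                   adet_grid.z_bot, 0.0, 100.0, 0.0)
        assert fw == 1.0 and fn == 1.0

    def test_zero_supply_full_stress(self, adet_grid, wheat):
        state = sow(CropState(), 1, wheat)
        hyd = adet_grid.hydraulics
        fw, fn, _ = water_n_stress(state, VARIANTS["ceres_like"], wheat,
                                   hyd.theta_pwp, hyd.theta_fc, hyd.theta_pwp,
                                   adet_grid.thickness_mm, adet_grid.z_top,
                                   adet_grid.z_bot, 5.0, 0.0, 5.0)
        assert fw == 0.0 and fn == 0.0

    def test_gecros_unstressed_until_wilting_point_ceres_not(self, adet_grid, wheat):
        hyd = adet_grid.hydraulics
        theta = self._theta_mid(adet_grid)
        state = sow(CropState(), 1, wheat)
        state.root_depth = 60.0
        demand = 5.0
        fw_g, _, _ = water_n_stress(state, VARIANTS["gecros_like"], wheat, theta,
                                    hyd.theta_fc, hyd.theta_pwp,
                                    adet_grid.thickness_mm, adet_grid.z_top,
                                    adet_grid.z_bot, demand, 1.0, 0.0)
        fw_c, _, _ = water_n_stress(state, VARIANTS["ceres_like"], wheat, theta,
                                    hyd.theta_fc, hyd.theta_pwp,
                                    adet_grid.thickness_mm, adet_grid.z_top,
                                    adet_grid.z_bot, demand, 1.0, 0.0)
        assert fw_g == 1.0
        assert fw_c < 1.0


class TestDailyGrowth:
    def test_no_radiation_no_assimilation(self, wheat):
        state = grow_season("ceres_like", wheat, days=30)
        before = state.cum_assimilation
        env = GrowthInputs(srad=0.0, tmean=18.0)
        out, _ = daily_growth(state, VARIANTS["ceres_like"], env, wheat)
        assert out.cum_assimilation == before
        # pools change only by senescence
        assert out.biomass <= state.biomass

    def test_grain_fraction_one_routes_all_assimilation_to_grain(self):
        params = wheat_genotype(grain_frac_max=1.0)
        state = grow_season("sucros_like", params, days=90)
        # push deep into grain filling so the allocation ramp is at 1.0
        state = state.__class__(**{**state.__dict__,
                                   "tt": params.tt_flowering + 0.7
                                   * (params.tt_maturity - params.tt_flowering),
                                   "stage": STAGE_GRAINFILL})
        env = GrowthInputs(srad=20.0, tmean=18.0)
        out, _ = daily_growth(state, VARIANTS["sucros_like"], env, params)
        gained = out.cum_assimilation - state.cum_assimilation
        assert out.grain - state.grain == pytest.approx(gained, rel=1e-12)

    def test_gecros_nitrogen_limitation_shifts_growth_to_roots(self, wheat):
        stressed = grow_season("gecros_like", wheat, days=60, f_n=0.4)
        unstressed = grow_season("gecros_like", wheat, days=60)
        assert stressed.root / stressed.biomass > unstressed.root / unstressed.biomass

    def test_carbon_bookkeeping_closes_exactly(self, wheat):
        for variant in VARIANTS:
            state = grow_season(variant, wheat)
            b0 = wheat.initial_biomass
            assert state.biomass - b0 == pytest.approx(
                state.cum_assimilation - state.cum_senesced, abs=1e-8)

    def test_nitrogen_bookkeeping_closes_exactly(self, wheat):
        for variant in VARIANTS:
            state = grow_season(variant, wheat)
            n0 = 0.6 * wheat.initial_biomass * wheat.leaf_n_conc \
                + 0.4 * wheat.initial_biomass * wheat.root_n_conc
            assert state.n_crop - n0 == pytest.approx(
                state.cum_n_uptake - state.cum_n_senesced, abs=1e-8)

    def test_harvest_index_bounded(self):
        rng = np.random.default_rng(7)
        for _ in range(8):
            params = wheat_genotype(
                tt_flowering=float(rng.uniform(700, 1200)),
                tt_maturity=float(rng.uniform(1500, 2200)),
                sla=float(rng.uniform(0.015, 0.028)))
            for variant in VARIANTS:
                state = grow_season(variant, params,
                                    tmean=float(rng.uniform(15, 20)))
                if state.above_ground > 0:
                    hi = state.grain / state.above_ground
                    assert hi <= 0.65

    def test_structural_spread_within_factor_two(self, wheat):
        yields = {v: grow_season(v, wheat).grain for v in VARIANTS}
        vals = np.array(list(yields.values()))
        assert vals.max() / vals.min() <= 2.0
        assert len(set(np.round(vals, 6))) == len(vals)  # not identical


class TestFinalize:
    def test_grain_n_percent_definition(self, wheat):
        state = sow(CropState(), 1, wheat)
        state.grain = 5000.0
        state.n_grain = 100.0
        state.flowering_doy = 60
        state.maturity_doy = 120
        out = finalize_season(state, wheat)
        assert out["grain_n_pct"] == pytest.approx(2.0)
        assert out["grain_yield"] == pytest.approx(5.0)

    def test_season_without_flowering_zero_yield(self, wheat):
        state = grow_season("ceres_like", wheat, days=20)
        out = finalize_season(state, wheat)
        assert out["grain_yield"] == 0.0

    def test_never_sown_rejected(self, wheat):
        with pytest.raises(ValueError, match="sown"):
            finalize_season(CropState(), wheat)
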