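"""Factorial ensemble construction, planting rule and season orchestration."""

import numpy as np
import pandas as pd
import pytest

from agroens.climate import PerturbationSpec
from agroens.ensemble import (EnsembleConfig, SeasonResult, build_ensemble,
                              run_ensemble, run_season)
from agroens.management import ManagementPlan, planting_date, planting_window
from agroens.synthetic import SiteClimatology, generate_weather
from agroens.weather import WeatherSeries


class TestBuildEnsemble:
    def test_default_axes_give_48_unique_members(self):
        configs = build_ensemble()
        assert len(configs) == 48
        assert len(set(c.id for c in configs)) == 48

    def test_each_crop_model_appears_in_12_members(self):
        configs = build_ensemble()
        for crop in ("ceres_like", "sucros_like", "spass_like", "gecros_like"):
            assert sum(c.crop_model == crop for c in configs) == 12

    def test_arbitrary_axes_exhaustive_and_duplicate_free(self):
        configs = build_ensemble(crop_models=("ceres_like", "gecros_like"),
                                 heat_models=("daisy_like",))
        assert len(configs) == 2 * 2 * 2 * 1
        assert len(set(configs)) == len(configs)

    def test_invalid_axis_value_rejected(self):
        with pytest.raises(ValueError):
            EnsembleConfig("dssat", "tipping", "soiln3", "leachn_like")


class TestPlantingWindow:
    def test_identical_dates_degenerate_window(self):
        assert planting_window([160, 160, 160]) == (160, 160)

    def test_mean_pm_2sd_hand_case(self):
        # DOYs 150/160/170: mean 160, sample SD 10 -> window (140, 180)
        assert planting_window([150, 160, 170]) == (140, 180)

    def test_start_never_after_end(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            doys = rng.integers(100, 250, size=rng.integers(2, 9))
            start, end = planting_window(doys)
            assert start <= end


def _weather_from_precip(precip, year=2001):
    n = len(precip)
    dates = pd.date_range(f"{year}-01-01", periods=n, freq="D")
    df = pd.DataFrame({"date": dates, "tmax": 25.0, "tmin": 10.0,
                       "precip": precip, "srad": 20.0, "wind": 2.0, "rh": 60.0})
    return WeatherSeries("synthetic", df)


def brute_force_planting(precip_by_doy, window, rain_sum=20.0, rain_window=3,
                         dry_max=10, lookahead=30, dry_mm=1.0):
    """Independent day-scan oracle for the rainfall planting rule."""
    start, end = window
    for d in range(start, end + 1):
        total = sum(precip_by_doy.get(d + i, 0.0) for i in range(rain_window))
        if total < rain_sum:
            continue
        bad = False
        for s in range(d + 1, d + lookahead + 1):
            # does a dry run longer than dry_max start here?
            run_len = 0
            t = s
            while t <= d + lookahead and precip_by_doy.get(t, 0.0) < dry_mm:
                run_len += 1
                t += 1
            if run_len > dry_max:
                bad = True
                break
        if not bad:
            return d
    return end


class TestPlantingDate:
    def test_immediate_trigger(self):
        precip = np.zeros(365)
        precip[120] = 25.0  # window day 1
        precip[124::5] = 8.0  # rain every 5th day afterwards
        wx = _weather_from_precip(precip)
        assert planting_date(wx, (121, 150), 2001) == 121

    def test_dry_season_falls_back_to_window_end(self):
        wx = _weather_from_precip(np.zeros(365))
        assert planting_date(wx, (121, 150), 2001) == 150

    def test_dry_spell_rejects_early_candidate(self):
        precip = np.zeros(365)
        # 3-day sum of 20 mm on DOY 123-125, then a 12-day dry run from DOY 130
        precip[122:125] = [8.0, 7.0, 5.0]
        precip[125:129] = 3.0
        precip[141::3] = 6.0  # resumes after the long dry spell
        wx = _weather_from_precip(precip)
        chosen = planting_date(wx, (123, 160), 2001)
        assert chosen > 123
        doys = wx.data["date"].dt.dayofyear.to_numpy()
        oracle = brute_force_planting(dict(zip(doys, precip)), (123, 160))
        assert chosen == oracle

    def test_agrees_with_brute_force_oracle_on_random_series(self):
        rng = np.random.default_rng(11)
        window = (130, 170)
        for _ in range(300):
            wet = rng.random(365) < rng.uniform(0.05, 0.6)
            precip = np.where(wet, rng.gamma(0.8, 8.0, 365), 0.0)
            wx = _weather_from_precip(precip)
            doys = wx.data["date"].dt.dayofyear.to_numpy()
            expected = brute_force_planting(dict(zip(doys, precip)), window)
            assert planting_date(wx, window, 2001) == expected

    def test_too_short_series_rejected(self):
        wx = _weather_from_precip(np.zeros(200))
        with pytest.raises(ValueError, match="too short"):
            planting_date(wx, (150, 190), 2001)


class TestRunSeason:
    CFG = EnsembleConfig("spass_like", "tipping", "daisy6", "daisy_like")

    def test_deterministic(self, adet_weather, adet_grid, wheat, mgmt):
        a = run_season(self.CFG, adet_weather, adet_grid, wheat, mgmt, None, 1982)
        b = run_season(self.CFG, adet_weather, adet_grid, wheat, mgmt, None, 1982)
        assert a == b

    def test_lgs_is_maturity_minus_planting(self, adet_weather, adet_grid,
                                            wheat, mgmt):
        r = run_season(self.CFG, adet_weather, adet_grid, wheat, mgmt, None, 1981)
        assert r.matured
        assert r.lgs == r.maturity_doy - r.planting_doy

    def test_annual_reinitialization_independence(self, adet_weather, adet_grid,
                                                  wheat, mgmt):
        """A year's result does not depend on which years ran before it."""
        alone = run_season(self.CFG, adet_weather, adet_grid, wheat, mgmt, None, 1983)
        run_season(self.CFG, adet_weather, adet_grid, wheat, mgmt, None, 1981)
        run_season(self.CFG, adet_weather, adet_grid, wheat, mgmt, None, 1982)
        again = run_season(self.CFG, adet_weather, adet_grid, wheat, mgmt, None, 1983)
        assert alone == again

    def test_fertilizer_raises_yield_on_poor_soil(self, adet_weather,
                                                  n_poor_grid, wheat, mgmt):
        fert = run_season(self.CFG, adet_weather, n_poor_grid, wheat, mgmt,
                          PerturbationSpec(n_fert=160.0), 1982)
        none = run_season(self.CFG, adet_weather, n_poor_grid, wheat, mgmt,
                          PerturbationSpec(n_fert=0.0), 1982)
        assert fert.grain_yield > none.grain_yield


class TestRunEnsemble:
    def test_row_count_is_product_of_axes(self, adet_weather, adet_grid,
                                          wheat, mgmt):
        configs = build_ensemble(crop_models=("ceres_like",),
                                 heat_models=("leachn_like",))
        df = run_ensemble(configs, {"c0": adet_weather}, None, [1981, 1982],
                          adet_grid, wheat, mgmt)
        assert len(df) == 1 * len(configs) * 1 * 2

    def test_empty_scenarios_labelled_baseline(self, adet_weather, adet_grid,
                                               wheat, mgmt):
        configs = build_ensemble(crop_models=("ceres_like",),
                                 water_models=("tipping",),
                                 som_models=("soiln3",),
                                 heat_models=("leachn_like",))
        df = run_ensemble(configs, {"c0": adet_weather}, [], [1981],
                          adet_grid, wheat, mgmt)
        assert (df["scenario_id"] == "baseline").all()

    def test_config_order_does_not_affect_table(self, adet_weather, adet_grid,
                                                wheat, mgmt):
        configs = build_ensemble(crop_models=("ceres_like", "gecros_like"),
                                 water_models=("tipping",),
                                 som_models=("soiln3",),
                                 heat_models=("leachn_like",))
        a = run_ensemble(configs, {"c0": adet_weather}, None, [1981],
                         adet_grid, wheat, mgmt)
        b = run_ensemble(list(reversed(configs)), {"c0": adet_weather}, None,
                         [1981], adet_grid, wheat, mgmt)
        pd.testing.assert_frame_equal(a, b)


class TestInterfaces:
    CFG = EnsembleConfig("ceres_like", "tipping", "soiln3", "leachn_like")

    def test_soil_profile_text_roundtrip(self, tmp_path):
        from agroens.soil import load_soil_fixture, soil_from_csv, soil_to_csv
        p = load_soil_fixture("Sinana")
        path = tmp_path / "soil.csv"
        soil_to_csv(p, path)
        q = soil_from_csv(path)
        assert q.site_id == "Sinana"
        assert [h.fc for h in q.horizons] == [h.fc for h in p.horizons]

    def test_daily_trace_collected(self, adet_weather, adet_grid, wheat, mgmt):
        trace = []
        run_season(self.CFG, adet_weather, adet_grid, wheat, mgmt, None, 1981,
                   trace_sink=trace)
        df = pd.DataFrame(trace)
        assert {"doy", "lai", "biomass", "f_water", "mineral_n"} <= set(df.columns)
        assert (df["lai"] >= 0).all()
        assert df["doy"].is_monotonic_increasing

    def test_run_ensemble_resumes_from_partial_table(self, adet_weather,
                                                     adet_grid, wheat, mgmt):
        configs = build_ensemble(crop_models=("ceres_like",),
                                 water_models=("tipping",),
                                 som_models=("soiln3",),
                                 heat_models=("leachn_like", "daisy_like"))
        full = run_ensemble(configs, {"c0": adet_weather}, None, [1981, 1982],
                            adet_grid, wheat, mgmt)
        part = run_ensemble(configs, {"c0": adet_weather}, None, [1981],
                            adet_grid, wheat, mgmt)
        resumed = run_ensemble(configs, {"c0": adet_weather}, None,
                               [1981, 1982], adet_grid, wheat, mgmt,
                               existing=part)
        pd.testing.assert_frame_equal(resumed, full)

    def test_soil_state_snapshot_frame(self, adet_grid):
        from agroens.soil import soil_state_frame
        from agroens.waterflow import initial_water_state
        w = initial_water_state(adet_grid)
        df = soil_state_frame(adet_grid, w.theta, np.full(adet_grid.n_cells, 20.0))
        assert len(df) == adet_grid.n_cells
        assert {"layer", "theta", "temperature_c"} <= set(df.columns)
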