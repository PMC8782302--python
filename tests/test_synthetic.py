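"""Weather generator, GCM emulation, observation noise and soil fixtures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agroens.soil import load_soil_fixture
from agroens.synthetic import (CULTIVARS, CropObservations, GcmDeltaSpec,
                               SiteClimatology, default_climatology,
                               generate_gcm_series, generate_observations,
                               generate_weather)


def _clim(**over):
    base = dict(
        site_id="t", monthly_tmax=[25.0] * 12, monthly_tmin=[10.0] * 12,
        monthly_rain=[80.0] * 12, wet_day_prob=[0.4] * 12,
    )
    base.update(over)
    return SiteClimatology(**base)


class TestGenerateWeather:
    def test_deterministic_for_same_seed(self):
        clim = default_climatology("Adet")
        a = generate_weather(clim, 2, seed=7)
        b = generate_weather(clim, 2, seed=7)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_zero_wet_probability_means_no_rain(self):
        wx = generate_weather(_clim(wet_day_prob=[0.0] * 12, monthly_rain=[0.0] * 12),
                              2, seed=1)
        assert (wx.data["precip"] == 0).all()

    def test_monthly_rain_total_converges(self):
        # July climatological total 300 mm; 200 simulated years within 5 %
        rain = [0.0] * 12
        rain[6] = 300.0
        prob = [0.0] * 12
        prob[6] = 0.6
        wx = generate_weather(_clim(monthly_rain=rain, wet_day_prob=prob), 200, seed=3)
        july = wx.data[wx.data["date"].dt.month == 7]
        mean_total = july.groupby(july["date"].dt.year)["precip"].sum().mean()
        assert mean_total == pytest.approx(300.0, rel=0.05)

    def test_invalid_climatology_rejected_with_parameter_name(self):
        with pytest.raises(ValueError, match="monthly_rain"):
            _clim(monthly_rain=[-5.0] * 12)
        with pytest.raises(ValueError, match="wet_day_prob"):
            _clim(wet_day_prob=[1.3] * 12)

    def test_leap_day_present(self):
        wx = generate_weather(_clim(), 1, seed=0, start_year=2000)
        assert len(wx) == 366

    @settings(max_examples=15, deadline=None)
    @given(seed=st.integers(0, 2 ** 31 - 1),
           rain=st.floats(0.0, 400.0),
           prob=st.floats(0.0, 1.0))
    def test_physical_invariants_hold(self, seed, rain, prob):
        wx = generate_weather(_clim(monthly_rain=[rain] * 12,
                                    wet_day_prob=[prob] * 12), 1, seed=seed)
        df = wx.data
        assert (df["tmax"] >= df["tmin"]).all()
        assert (df["precip"] >= 0).all()
        assert (df["srad"] >= 0).all()
        assert df["rh"].between(0, 100).all()


class TestGcmEmulation:
    def test_zero_deltas_zero_noise_future_equals_historical(self, adet_weather):
        spec = GcmDeltaSpec.uniform("g", 0.0, 0.0, 0.0)
        hist, fut = generate_gcm_series(adet_weather, spec, seed=1)
        assert np.allclose(hist.data["tmax"], fut.data["tmax"])
        assert np.allclose(hist.data["precip"], fut.data["precip"])
        # zero noise: historical reproduces the baseline
        assert np.allclose(hist.data["tmax"], adet_weather.data["tmax"])

    def test_additive_temperature_delta_is_exact(self, adet_weather):
        spec = GcmDeltaSpec.uniform("g", 1.3, 1.3, 0.0)
        hist, fut = generate_gcm_series(adet_weather, spec, seed=1)
        diff = fut.data["tmax"].mean() - hist.data["tmax"].mean()
        assert diff == pytest.approx(1.3, abs=1e-12)

    def test_multiplicative_precip_delta_is_exact(self, adet_weather):
        spec = GcmDeltaSpec.uniform("g", 0.0, 0.0, 0.07)
        hist, fut = generate_gcm_series(adet_weather, spec, seed=1)
        assert fut.data["precip"].sum() == pytest.approx(
            1.07 * hist.data["precip"].sum(), rel=1e-12)

    def test_deterministic_part_invertible_with_noise(self, adet_weather):
        spec = GcmDeltaSpec.uniform("g", 1.2, 1.4, 0.15, noise_scale=0.4)
        hist, fut = generate_gcm_series(adet_weather, spec, seed=5)
        month = fut.data["date"].dt.month.to_numpy()
        recovered_t = fut.data["tmax"].to_numpy() - np.asarray(spec.d_tmax)[month - 1]
        recovered_p = fut.data["precip"].to_numpy() / (1.0 + np.asarray(spec.d_precip)[month - 1])
        assert np.allclose(recovered_t, hist.data["tmax"], atol=1e-10)
        assert np.allclose(recovered_p, hist.data["precip"], atol=1e-10)

    def test_precip_removal_beyond_total_rejected(self):
        with pytest.raises(ValueError, match="d_precip"):
            GcmDeltaSpec.uniform("g", 0.0, 0.0, -1.0)


class _FakeSeason:
    def __init__(self, year, p, f, m, y):
        self.year, self.planting_doy, self.flowering_doy = year, p, f
        self.maturity_doy, self.grain_yield = m, y


class TestObservations:
    def _truth(self, n=6):
        return [_FakeSeason(2000 + i, 150, 220, 270, 4.0) for i in range(n)]

    def test_zero_noise_reproduces_truth(self):
        obs = generate_observations(self._truth(), (0.0, 0.0), seed=0)
        assert (obs.data["flowering_doy"] == 220).all()
        assert (obs.data["grain_yield"] == 4.0).all()

    def test_yield_noise_sd_recovered(self):
        obs = generate_observations(self._truth(1000), (0.0, 0.3), seed=2)
        sd = (obs.data["grain_yield"] - 4.0).std()
        assert sd == pytest.approx(0.3, rel=0.10)

    def test_ordering_invariant_enforced(self):
        truth = [_FakeSeason(2000, 150, 152, 154, 4.0)]  # tight dates
        for seed in range(30):
            obs = generate_observations(truth, (5.0, 0.0), seed=seed)
            row = obs.data.iloc[0]
            assert row.planting_doy < row.flowering_doy < row.maturity_doy

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            generate_observations([], (1.0, 0.1), seed=0)


class TestSoilFixtures:
    def test_adet_top_horizon_values(self):
        p = load_soil_fixture("Adet")
        h = p.horizons[0]
        assert (h.depth_top, h.depth_bottom) == (0, 5)
        assert h.fc == 44.3 and h.pwp == 31.5 and h.oc == 4.17

    def test_kulumsa_structure(self):
        p = load_soil_fixture("Kulumsa")
        assert len(p.horizons) == 6
        assert p.depth == 150
        assert all(h.ph == 5.3 for h in p.horizons)

    def test_sinana_mid_horizon(self):
        p = load_soil_fixture("Sinana")
        h = next(h for h in p.horizons if h.depth_top == 30)
        assert h.bd == 1.30 and h.cec == 47

    def test_unknown_site_lists_valid_names(self):
        with pytest.raises(ValueError, match="Adet"):
            load_soil_fixture("Gondar")


def test_cultivar_pathway_follows_crop():
    assert CULTIVARS["Shina"].pathway == "C3"
    assert CULTIVARS["Wenchi"].pathway == "C4"
    assert CULTIVARS["Medawolabu"].days_to_maturity == (136, 143)


class TestConfigFiles:
    def test_roundtrip_yaml_config(self, tmp_path):
        from agroens.config import load_genotype, load_management, load_scenarios
        cfg = tmp_path / "study.yaml"
        cfg.write_text(
            "genotype:\n"
            "  crop: maize\n"
            "  tt_flowering: 720\n"
            "management:\n"
            "  planting_window: [115, 150]\n"
            "  kc: 1.1\n"
            "  fertilizer_splits: [[0, 0.6], [25, 0.4]]\n"
            "scenarios:\n"
            "  - {dT: 2, dP: -0.25, co2: 540, n_fert: 160}\n"
            "  - {dT: 0, dP: 0}\n")
        gen = load_genotype(cfg)
        assert gen.pathway == "C4" and gen.tt_flowering == 720
        mgmt = load_management(cfg)
        assert mgmt.planting_window == (115, 150)
        assert mgmt.fertilizer_splits == ((0, 0.6), (25, 0.4))
        scen = load_scenarios(cfg)
        assert len(scen) == 2 and scen[0].co2 == 540
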