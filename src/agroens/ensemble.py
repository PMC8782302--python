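"""The factorial multi-model ensemble and the season/ensemble runners.

An ensemble member couples one choice on each of four submodel axes:

* crop growth: ceres_like | sucros_like | spass_like | gecros_like
* soil water: richards | tipping
* soil organic matter: soiln3 | daisy6
* soil heat: leachn_like | daisy_like | shaw_like

The full Cartesian product gives 4 x 2 x 2 x 3 = 48 members.  A season run
re-initializes all soil and crop state (same initial conditions every year),
decides the planting date by the rainfall rule, then loops daily:
soil heat -> soil water (with FAO-56 ET demand split by canopy cover) ->
SOM turnover and mineral N -> crop growth.  Scenario perturbations enter as
temperature offsets and precipitation factors on the weather, CO2 on the
crop, and the N rate on the fertilizer events.
"""

from __future__ import annotations

import itertools
import logging
import time
from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import crop as crop_mod
from .climate import PerturbationSpec, apply_perturbation
from .crop import (CropState, GenotypeParams, GrowthInputs, VARIANTS,
                   daily_growth, finalize_season, intercepted_fraction, sow,
                   step_phenology, water_n_stress)
from .fao56 import Et0Inputs, et0_fao56
from .management import ManagementPlan, planting_date
from .nitrogen import (MineralNState, init_som_from_profile, initial_mineral_n,
                       moisture_modifier, step_mineral_n, step_som_turnover)
from .soil import SoilGrid
from .soilheat import SoilHeatColumn
from .waterflow import SoilWaterState, initial_water_state, step_water
from .weather import WeatherSeries

CROP_MODELS = ("ceres_like", "sucros_like", "spass_like", "gecros_like")
WATER_MODELS = ("richards", "tipping")
SOM_MODELS = ("soiln3", "daisy6")
HEAT_MODELS = ("leachn_like", "daisy_like", "shaw_like")

RESIDUE_CARBON_FRACTION = 0.45  # kg C per kg senesced dry matter
N_ACCESS_PER_DAY = 0.5  # fraction of rooted-zone mineral N accessible daily

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnsembleConfig:
    crop_model: str
    water_model: str
    som_model: str
    heat_model: str

    def __post_init__(self) -> None:
        for value, axis in ((self.crop_model, CROP_MODELS),
                            (self.water_model, WATER_MODELS),
                            (self.som_model, SOM_MODELS),
                            (self.heat_model, HEAT_MODELS)):
            if value not in axis:
                raise ValueError(f"{value!r} not in axis {axis}")

    @property
    def id(self) -> str:
        return "|".join((self.crop_model, self.water_model,
                         self.som_model, self.heat_model))


def build_ensemble(crop_models=CROP_MODELS, water_models=WATER_MODELS,
                   som_models=SOM_MODELS, heat_models=HEAT_MODELS
                   ) -> list[EnsembleConfig]:
    """Full factorial product over the four submodel axes.

    Ordering is the nested product with the crop-model axis outermost and
    the heat-model axis innermost (stable and documented).
    """
    return [EnsembleConfig(*combo) for combo in
            itertools.product(crop_models, water_models, som_models, heat_models)]


@dataclass
class SeasonResult:
    year: int
    config_id: str
    scenario_id: str
    grain_yield: float  # t/ha dry matter
    grain_n_pct: float
    planting_doy: int
    flowering_doy: int | None
    maturity_doy: int | None
    lgs: int | None  # length of growing season, days
    n_leached: float  # kg N/ha cumulative
    et_total: float  # mm (E + T)
    drainage_total: float  # mm
    water_balance_residual: float  # mm
    c_balance_residual: float  # kg C/ha (SOM subsystem)
    n_balance_residual: float  # kg N/ha (mineral N subsystem)
    crop_n_residual: float  # kg N/ha (crop subsystem)
    cum_water_input: float  # mm, for relative closure checks
    cum_c_flux: float  # kg C/ha, |inputs| + |outputs| of the SOM system
    cum_n_flux: float  # kg N/ha, gross mineral-N turnover
    matured: bool = True


def run_season(config: EnsembleConfig, weather: WeatherSeries, grid: SoilGrid,
               genotype: GenotypeParams, mgmt: ManagementPlan,
               scenario: PerturbationSpec | None, year: int,
               spinup_days: int = 15,
               trace_sink: list | None = None) -> SeasonResult:
    """Simulate one cropping season under one ensemble member.

    State is re-initialized from the management plan (annual reset); the
    daily loop runs from shortly before the planting window to crop maturity
    (or the end of the year, flagged if maturity is not reached).  When
    ``trace_sink`` is a list, one dict of daily state diagnostics is appended
    per simulated day (for debugging; convert with ``pd.DataFrame``).
    """
    scenario_id = "baseline" if scenario is None else scenario.label
    scenario = scenario or PerturbationSpec()
    variant = VARIANTS[config.crop_model]

    year_df = weather.year_slice(year)
    if len(year_df) == 0:
        raise ValueError(f"no weather data for year {year}")
    wx = WeatherSeries(weather.site_id, year_df)
    if scenario.dT != 0.0 or scenario.dP != 0.0:
        wx = apply_perturbation(wx, scenario)
    df = wx.data
    doys = df["date"].dt.dayofyear.to_numpy()
    tmax = df["tmax"].to_numpy()
    tmin = df["tmin"].to_numpy()
    precip = df["precip"].to_numpy()
    srad = df["srad"].to_numpy()
    wind = df["wind"].to_numpy() if "wind" in df else np.full(len(df), 2.0)
    rh = df["rh"].to_numpy() if "rh" in df else np.full(len(df), np.nan)
    tmean = 0.5 * (tmax + tmin)

    plant_doy = planting_date(wx, mgmt.planting_window, year)

    # --- initial state (same every year by construction) -------------------
    water = initial_water_state(grid, mgmt.initial_water_fraction)
    som = init_som_from_profile(grid, config.som_model)
    mineral = initial_mineral_n(grid, mgmt.initial_no3)
    heat_col = SoilHeatColumn(grid, config.heat_model,
                              t_mean=float(np.mean(tmean)),
                              t_amplitude=max(0.5, float(np.ptp(
                                  pd.Series(tmean).rolling(30, min_periods=1).mean())) / 2.0),
                              phase_doy=float(doys[np.argmax(
                                  pd.Series(tmean).rolling(30, min_periods=1).mean().to_numpy())]))
    heat = heat_col.initial_state()
    crop_state = CropState()

    fert_doys = {plant_doy + off: frac * scenario.n_fert
                 for off, frac in mgmt.fertilizer_splits}

    hyd = grid.hydraulics
    start_idx = int(np.searchsorted(doys, max(doys[0], mgmt.planting_window[0] - spinup_days)))
    weekly = deque(maxlen=7)

    cum = dict(infil=0.0, drain=0.0, evap=0.0, transp=0.0, caprise=0.0,
               runoff=0.0, precip=0.0, leached=0.0, fert=0.0, min_n=0.0,
               min_abs=0.0, uptake=0.0, resp_c=0.0, residue_c=0.0, deficit=0.0)
    storage0 = water.storage_mm(grid)
    mineral0 = mineral.total
    som_c0 = som.total_c
    som_n0 = som.total_n
    residue_n_to_som = 0.0

    prev_drain_mm = 0.0
    prev_evap_mm = 0.0
    matured = False

    for i in range(start_idx, len(df)):
        doy = int(doys[i])
        weekly.append(tmean[i])
        weekly_mean = float(np.mean(weekly))

        # sowing
        if crop_state.stage == crop_mod.STAGE_PRESOW and doy >= plant_doy:
            crop_state = sow(crop_state, doy, genotype)

        # reference and crop evapotranspiration
        et0, etc = et0_fao56(Et0Inputs(
            tmax=float(tmax[i]), tmin=float(tmin[i]), srad=float(srad[i]),
            wind=float(wind[i]), latitude=mgmt.latitude, elevation=mgmt.elevation,
            doy=doy, rh=None if np.isnan(rh[i]) else float(rh[i]), kc=mgmt.kc))
        cover = intercepted_fraction(crop_state.lai, genotype.k_ext) \
            if crop_state.lai > 0 else 0.0
        evap_demand = et0 * (1.0 - cover)
        transp_total = etc * cover

        # soil heat (uses yesterday's water fluxes)
        heat = heat_col.step(heat, float(tmean[i]), weekly_mean, doy, water.theta,
                             water_flux_mm=prev_drain_mm, evaporation_mm=prev_evap_mm)
        soil_temp = heat.temperature[:grid.n_cells]

        # stress factors and per-layer transpiration demand
        growing = crop_state.stage in (crop_mod.STAGE_VEGETATIVE,
                                       crop_mod.STAGE_GRAINFILL)
        if growing:
            rooted = crop_mod.root_fractions(crop_state, variant, grid.z_top, grid.z_bot)
            n_accessible = N_ACCESS_PER_DAY * float(
                ((mineral.no3 + mineral.nh4) * (rooted > 0)).sum())
            # potential N demand estimated from an unstressed growth increment
            n_demand_est = max(1e-9, 0.03 * max(crop_state.biomass * 0.06, 10.0))
            f_water, f_n, supply = water_n_stress(
                crop_state, variant, genotype, water.theta, hyd.theta_fc,
                hyd.theta_pwp, grid.thickness_mm, grid.z_top, grid.z_bot,
                transp_total, n_accessible, n_demand_est)
            transp_actual = transp_total * f_water
            s = supply.sum()
            transp_per_layer = supply / s * transp_actual if s > 0 \
                else np.zeros(grid.n_cells)
        else:
            f_water = f_n = 1.0
            n_accessible = 0.0
            transp_per_layer = np.zeros(grid.n_cells)

        # soil water
        water = step_water(config.water_model, water, grid, float(precip[i]),
                           evap_demand, transp_per_layer)
        fl = water.fluxes
        cum["infil"] += fl.infiltration
        cum["drain"] += fl.drainage
        cum["evap"] += fl.evaporation
        cum["transp"] += fl.transpiration
        cum["caprise"] += fl.capillary_rise
        cum["runoff"] += fl.runoff
        cum["precip"] += precip[i]
        prev_drain_mm = fl.drainage
        prev_evap_mm = fl.evaporation

        # SOM turnover and net mineralization
        f_moist = moisture_modifier(water.theta, hyd.theta_r, hyd.theta_fc,
                                    hyd.theta_s)
        som_c_before = som.total_c
        som, net_min = step_som_turnover(som, soil_temp, f_moist)
        cum["resp_c"] += som_c_before - som.total_c

        # crop phenology and growth
        uptake_total = 0.0
        if growing:
            crop_state = step_phenology(crop_state, float(tmean[i]), genotype, doy)
            if crop_state.stage == crop_mod.STAGE_MATURE:
                matured = True
            env = GrowthInputs(srad=float(srad[i]), tmean=float(tmean[i]),
                               co2=scenario.co2, f_water=f_water, f_n=f_n,
                               n_available=n_accessible)
            crop_state, uptake_total = daily_growth(crop_state, variant, env, genotype)
            if crop_state.senesced_today > 0:
                res_c = RESIDUE_CARBON_FRACTION * crop_state.senesced_today
                som.add_residue(0, res_c)
                cum["residue_c"] += res_c
                residue_n_to_som += res_c / som.cn[som.litter_pool]

        # distribute realized uptake over rooted layers by mineral N stock
        stocks = (mineral.no3 + mineral.nh4)
        if growing and uptake_total > 0:
            w = stocks * (rooted > 0)
            tw = w.sum()
            uptake_per_layer = w / tw * uptake_total if tw > 0 else np.zeros_like(w)
        else:
            uptake_per_layer = np.zeros(grid.n_cells)

        fert_today = fert_doys.get(doy, 0.0)
        mineral = step_mineral_n(mineral, grid, net_min, fert_today,
                                 uptake_per_layer,
                                 fl.flux_down if fl.flux_down is not None
                                 else np.zeros(grid.n_cells),
                                 water.theta)
        nf = mineral.fluxes
        cum["leached"] += nf.leached
        cum["fert"] += nf.fertilizer
        cum["min_n"] += nf.net_mineralization
        cum["min_abs"] += abs(nf.net_mineralization)
        cum["uptake"] += nf.uptake
        cum["deficit"] += nf.immobilization_deficit

        if trace_sink is not None:
            trace_sink.append({
                "year": year, "doy": doy, "stage": crop_state.stage,
                "tt": crop_state.tt, "lai": crop_state.lai,
                "biomass": crop_state.biomass, "grain": crop_state.grain,
                "f_water": f_water, "f_n": f_n, "et0": et0,
                "theta_top": float(water.theta[0]),
                "soil_temp_top": float(soil_temp[0]),
                "mineral_n": mineral.total,
            })

        if crop_state.stage == crop_mod.STAGE_MATURE:
            break

    # --- balances -----------------------------------------------------------
    storage1 = water.storage_mm(grid)
    water_residual = (storage1 - storage0) - (
        cum["infil"] + cum["caprise"] - cum["drain"] - cum["evap"] - cum["transp"])
    c_residual = (som.total_c - som_c0) - (cum["residue_c"] - cum["resp_c"])
    n_min_residual = (mineral.total - mineral0) - (
        cum["min_n"] + cum["fert"] - cum["uptake"] - cum["leached"])
    if crop_state.planting_doy is None:
        crop_n_residual = 0.0
    else:
        crop_n_residual = (crop_state.n_crop - _initial_crop_n(genotype)
                           - (crop_state.cum_n_uptake - crop_state.cum_n_senesced))

    out = finalize_season(crop_state, genotype) if crop_state.planting_doy is not None \
        else {"grain_yield": 0.0, "grain_n_pct": 0.0, "planting_doy": plant_doy,
              "flowering_doy": None, "maturity_doy": None}
    maturity = out["maturity_doy"] if matured else None
    lgs = (maturity - out["planting_doy"]) if maturity is not None else None

    return SeasonResult(
        year=year, config_id=config.id,
        scenario_id=scenario_id,
        grain_yield=out["grain_yield"], grain_n_pct=out["grain_n_pct"],
        planting_doy=out["planting_doy"], flowering_doy=out["flowering_doy"],
        maturity_doy=maturity, lgs=lgs,
        n_leached=cum["leached"],
        et_total=cum["evap"] + cum["transp"], drainage_total=cum["drain"],
        water_balance_residual=water_residual,
        c_balance_residual=c_residual,
        n_balance_residual=n_min_residual,
        crop_n_residual=crop_n_residual,
        cum_water_input=cum["infil"] + cum["caprise"],
        cum_c_flux=cum["residue_c"] + cum["resp_c"],
        cum_n_flux=cum["min_abs"] + cum["fert"] + cum["uptake"] + cum["leached"],
        matured=matured,
    )


def _initial_crop_n(params: GenotypeParams) -> float:
    b0 = params.initial_biomass
    return 0.6 * b0 * params.leaf_n_conc + 0.4 * b0 * params.root_n_conc


def run_ensemble(configs, weather_map: dict[str, WeatherSeries], scenarios,
                 years, grid: SoilGrid, genotype: GenotypeParams,
                 mgmt: ManagementPlan,
                 existing: pd.DataFrame | None = None) -> pd.DataFrame:
    """Run the factorial ensemble over climates, scenarios and years.

    Returns a tidy long table keyed by (climate_id, config_id, scenario_id,
    year); failed seasons are recorded with ``matured = False`` rather than
    dropped.  Row order is independent of the iteration order of ``configs``
    (the table is sorted on the keys).  Passing a previous (partial) results
    table as ``existing`` resumes the run: already-computed keys are kept,
    only the missing ones are simulated.
    """
    configs = list(configs)
    if not configs:
        raise ValueError("no ensemble configs")
    scenario_list = list(scenarios) if scenarios else [None]
    done: set = set()
    rows = []
    if existing is not None and len(existing):
        done = set(map(tuple, existing[["climate_id", "config_id",
                                        "scenario_id", "year"]].to_numpy()))
        rows.extend(existing.to_dict("records"))
    for climate_id, weather in weather_map.items():
        for config in configs:
            for scenario in scenario_list:
                for year in years:
                    scenario_id = "baseline" if scenario is None else scenario.label
                    if (climate_id, config.id, scenario_id, year) in done:
                        continue
                    t0 = time.perf_counter()
                    r = run_season(config, weather, grid, genotype, mgmt,
                                   scenario, year)
                    logger.debug("season climate=%s config=%s scenario=%s "
                                 "year=%d yield=%.3f t/ha in %.3f s",
                                 climate_id, config.id, scenario_id, year,
                                 r.grain_yield, time.perf_counter() - t0)
                    rows.append({
                        "climate_id": climate_id,
                        "config_id": r.config_id,
                        "crop_model": config.crop_model,
                        "water_model": config.water_model,
                        "som_model": config.som_model,
                        "heat_model": config.heat_model,
                        "scenario_id": r.scenario_id,
                        "year": r.year,
                        "grain_yield": r.grain_yield,
                        "grain_n_pct": r.grain_n_pct,
                        "planting_doy": r.planting_doy,
                        "flowering_doy": r.flowering_doy,
                        "maturity_doy": r.maturity_doy,
                        "lgs": r.lgs,
                        "n_leached": r.n_leached,
                        "et_total": r.et_total,
                        "drainage_total": r.drainage_total,
                        "water_balance_residual": r.water_balance_residual,
                        "cum_water_input": r.cum_water_input,
                        "c_balance_residual": r.c_balance_residual,
                        "cum_c_flux": r.cum_c_flux,
                        "n_balance_residual": r.n_balance_residual,
                        "crop_n_residual": r.crop_n_residual,
                        "cum_n_flux": r.cum_n_flux,
                        "matured": r.matured,
                    })
    df = pd.DataFrame(rows)
    return df.sort_values(["climate_id", "config_id", "scenario_id", "year"],
                          kind="mergesort").reset_index(drop=True)
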