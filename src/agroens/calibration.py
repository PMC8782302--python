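"""Two-step genotype calibration as a Model/Results pair.

:class:`CropSystemModel` binds observations, weather, soil and one ensemble
configuration; its :meth:`fit` runs the two-step sum-of-squared-errors
calibration — first the thermal-time parameters controlling phenology
against observed flowering and maturity dates, then (with those fixed) the
growth-efficiency parameter against observed yields — and returns a
:class:`CalibrationResult` carrying the estimates, goodness-of-fit metrics
and a ``summary()`` table.

The optimizer is a bounded derivative-free simplex (Nelder-Mead) with
seeded multistarts; phenology SSE is evaluated on continuous threshold
crossing times (the fractional day on which accumulated thermal time passes
the threshold), which smooths the integer-day objective, with observed dates
taken at the half-day of their calendar day.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .crop import GenotypeParams
from .ensemble import EnsembleConfig, run_season
from .management import ManagementPlan
from .metrics import MetricsReport, metrics
from .climate import PerturbationSpec
from .soil import SoilGrid
from .synthetic import CropObservations
from .weather import WeatherSeries


def phenology_crossings(weather: WeatherSeries, year: int, planting_doy: int,
                        params: GenotypeParams) -> tuple[float, float]:
    """Continuous flowering/maturity crossing times (day of year).

    Thermal time accumulates from the planting day (matching the season
    runner); the crossing time interpolates linearly within the day on which
    the threshold is passed, so the integer simulated date is its ceiling.
    """
    df = weather.year_slice(year)
    doys = df["date"].dt.dayofyear.to_numpy()
    tmean = 0.5 * (df["tmax"].to_numpy() + df["tmin"].to_numpy())
    start = int(np.searchsorted(doys, planting_doy))
    tt_daily = np.maximum(0.0, tmean[start:] - params.t_base)
    cum = np.cumsum(tt_daily)

    def crossing(threshold: float) -> float:
        idx = int(np.searchsorted(cum, threshold))
        if idx >= len(cum):
            return float(planting_doy + len(cum) + 1)  # beyond the data
        prev = cum[idx - 1] if idx > 0 else 0.0
        step = cum[idx] - prev
        frac = (threshold - prev) / step if step > 0 else 1.0
        return planting_doy + idx - 1 + frac

    return crossing(params.tt_flowering), crossing(params.tt_maturity)


def _multistart_minimize(objective, x0s, bounds):
    best = None
    for x0 in x0s:
        res = minimize(objective, x0, method="Nelder-Mead", bounds=bounds,
                       options={"xatol": 1e-3, "fatol": 1e-8, "maxiter": 400})
        if best is None or res.fun < best.fun:
            best = res
    return best


def calibrate_phenology(config: EnsembleConfig, observations: CropObservations,
                        weather: WeatherSeries, params: GenotypeParams,
                        bounds: dict[str, tuple[float, float]] | None = None,
                        seed: int = 0) -> tuple[GenotypeParams, dict]:
    """Step 1: estimate thermal-time thresholds from flowering/maturity dates."""
    obs = observations.data
    if len(obs) < 2:
        raise ValueError("need at least 2 seasons of phenology observations")
    bounds = bounds or {"tt_flowering": (300.0, 2500.0), "tt_maturity": (500.0, 4000.0)}
    lo = np.array([bounds["tt_flowering"][0], bounds["tt_maturity"][0]])
    hi = np.array([bounds["tt_flowering"][1], bounds["tt_maturity"][1]])
    rng = np.random.default_rng(seed)

    rows = list(obs.itertuples())

    def objective(x):
        ttf, ttm = x
        if ttm <= ttf:
            return 1e12 + (ttf - ttm) ** 2
        p = replace(params, tt_flowering=float(ttf), tt_maturity=float(ttm))
        sse = 0.0
        for r in rows:
            f_sim, m_sim = phenology_crossings(weather, int(r.year),
                                               int(r.planting_doy), p)
            sse += (f_sim - (r.flowering_doy - 0.5)) ** 2
            sse += (m_sim - (r.maturity_doy - 0.5)) ** 2
        return sse

    x0s = [np.array([params.tt_flowering, params.tt_maturity])]
    for _ in range(2):
        x0s.append(lo + rng.random(2) * (hi - lo))
    x0s = [np.clip(np.sort(x), lo, hi) for x in x0s]
    best = _multistart_minimize(objective, x0s, list(zip(lo, hi)))

    fitted = replace(params, tt_flowering=float(best.x[0]),
                     tt_maturity=float(best.x[1]))
    at_bounds = bool(np.any(np.isclose(best.x, lo)) or np.any(np.isclose(best.x, hi)))
    return fitted, {"sse": float(best.fun), "at_bounds": at_bounds,
                    "n_seasons": len(rows)}


def calibrate_growth(config: EnsembleConfig, observations: CropObservations,
                     weather: WeatherSeries, grid: SoilGrid,
                     params: GenotypeParams, mgmt: ManagementPlan,
                     bounds: tuple[float, float] = (0.3, 3.0),
                     seed: int = 0) -> tuple[GenotypeParams, dict]:
    """Step 2: estimate the growth-efficiency scale against observed yields.

    The phenology parameters from step 1 stay fixed (bit-identical); a
    single multiplicative scale on the variant's efficiency currency (RUE or
    the leaf photosynthetic capacity) is estimated by SSE on yields.
    """
    obs = observations.data
    rng = np.random.default_rng(seed)
    years = obs["year"].astype(int).tolist()

    def simulate_yields(p: GenotypeParams) -> np.ndarray:
        sims = []
        for y in years:
            r = run_season(config, weather, grid, p, mgmt, None, y)
            sims.append(r.grain_yield)
        return np.asarray(sims)

    obs_yield = obs["grain_yield"].to_numpy()

    def with_scale(s: float) -> GenotypeParams:
        return replace(params, rue=params.rue * s, amax=params.amax * s)

    def objective(x):
        return float(np.sum((simulate_yields(with_scale(float(x[0]))) - obs_yield) ** 2))

    x0s = [np.array([1.0]), np.array([rng.uniform(*bounds)])]
    best = _multistart_minimize(objective, x0s, [bounds])
    scale = float(best.x[0])
    fitted = with_scale(scale)
    at_bounds = bool(np.isclose(scale, bounds[0]) or np.isclose(scale, bounds[1]))
    return fitted, {"sse": float(best.fun), "scale": scale, "at_bounds": at_bounds}


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------
@dataclass
class CalibrationResult:
    """Estimates and diagnostics of a fitted :class:`CropSystemModel`."""

    model: "CropSystemModel"
    params: GenotypeParams
    phenology_report: dict
    growth_report: dict
    phenology_metrics: dict[str, MetricsReport]
    yield_metrics: MetricsReport
    fitted_yields: np.ndarray

    def summary(self) -> str:
        p = self.params
        lines = [
            "Crop system calibration (two-step SSE)",
            "=" * 46,
            f"ensemble member : {self.model.config.id}",
            f"seasons         : {len(self.model.observations)}",
            "",
            "Step 1 - phenology (thermal time, deg C d)",
            f"  tt_flowering  : {p.tt_flowering:9.1f}",
            f"  tt_maturity   : {p.tt_maturity:9.1f}",
            f"  SSE (days^2)  : {self.phenology_report['sse']:9.2f}"
            + ("   [at bounds]" if self.phenology_report["at_bounds"] else ""),
        ]
        for name, m in self.phenology_metrics.items():
            lines.append(f"  {name:<13s}: RMSE {m.rmse:5.2f} d, r {m.r:5.3f}, "
                         f"NSE {m.nse:6.3f}, PBIAS {m.pbias:6.2f}%")
        lines += [
            "",
            "Step 2 - growth (efficiency scale on RUE/Amax)",
            f"  scale         : {self.growth_report['scale']:9.3f}"
            + ("   [at bounds]" if self.growth_report["at_bounds"] else ""),
            f"  yield RMSE    : {self.yield_metrics.rmse:9.3f} t/ha",
            f"  yield NSE     : {self.yield_metrics.nse:9.3f}",
            f"  yield PBIAS   : {self.yield_metrics.pbias:9.2f} %",
        ]
        return "\n".join(lines)

    def simulate(self, weather: WeatherSeries, years,
                 scenario: PerturbationSpec | None = None) -> pd.DataFrame:
        """Run seasons with the fitted parameters."""
        rows = []
        for y in years:
            r = run_season(self.model.config, weather, self.model.grid,
                           self.params, self.model.mgmt, scenario, int(y))
            rows.append(r.__dict__)
        return pd.DataFrame(rows)


class CropSystemModel:
    """One ensemble member bound to observations, weather and soil.

    Parameters
    ----------
    observations : CropObservations
        Per-season planting/flowering/maturity dates and yields.
    weather : WeatherSeries
        Daily weather covering all observation years.
    grid : SoilGrid
        Discretized soil profile.
    config : EnsembleConfig
        The submodel combination to calibrate.
    genotype : GenotypeParams
        Starting parameter set (priors / defaults for the cultivar).
    mgmt : ManagementPlan
        Management assumptions used in growth-step simulations.
    """

    def __init__(self, observations: CropObservations, weather: WeatherSeries,
                 grid: SoilGrid, config: EnsembleConfig,
                 genotype: GenotypeParams, mgmt: ManagementPlan):
        self.observations = observations
        self.weather = weather
        self.grid = grid
        self.config = config
        self.genotype = genotype
        self.mgmt = mgmt

    @classmethod
    def from_dataframe(cls, obs_df: pd.DataFrame, weather: WeatherSeries,
                       grid: SoilGrid, config: EnsembleConfig,
                       genotype: GenotypeParams, mgmt: ManagementPlan
                       ) -> "CropSystemModel":
        return cls(CropObservations(obs_df), weather, grid, config, genotype, mgmt)

    def fit(self, seed: int = 0, skip_growth: bool = False) -> CalibrationResult:
        """Two-step calibration; returns a :class:`CalibrationResult`."""
        fitted, phen_report = calibrate_phenology(
            self.config, self.observations, self.weather, self.genotype, seed=seed)

        obs = self.observations.data
        f_sim, m_sim = [], []
        for r in obs.itertuples():
            f, m = phenology_crossings(self.weather, int(r.year),
                                       int(r.planting_doy), fitted)
            f_sim.append(np.ceil(f))
            m_sim.append(np.ceil(m))
        phen_metrics = {
            "flowering": metrics(f_sim, obs["flowering_doy"].to_numpy()),
            "maturity": metrics(m_sim, obs["maturity_doy"].to_numpy()),
        }

        if skip_growth:
            growth_report = {"sse": float("nan"), "scale": 1.0, "at_bounds": False}
            final = fitted
        else:
            final, growth_report = calibrate_growth(
                self.config, self.observations, self.weather, self.grid,
                fitted, self.mgmt, seed=seed)
        sims = []
        for y in obs["year"].astype(int):
            sims.append(run_season(self.config, self.weather, self.grid, final,
                                   self.mgmt, None, y).grain_yield)
        fitted_yields = np.asarray(sims)
        yield_metrics = metrics(fitted_yields, obs["grain_yield"].to_numpy())
        return CalibrationResult(self, final, phen_report, growth_report,
                                 phen_metrics, yield_metrics, fitted_yields)
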