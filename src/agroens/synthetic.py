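"""Synthetic inputs: stochastic weather, emulated climate projections,
noisy crop observations and cultivar descriptors.

Every generator is a pure function of its parameters and a seed, so the whole
pipeline is testable without external downloads.  The weather generator is a
minimal standard structure: rainfall occurrence by a first-order two-state
Markov chain per calendar month, wet-day amounts from a gamma distribution,
temperatures as monthly climatological means plus autocorrelated noise, and
solar radiation as a clear-sky curve scaled down on wet (cloudy) days.

Climate projections are emulated rather than downloaded: a "historical" GCM
run is the observed baseline plus distortions (so bias correction has work to
do), and the "future" run adds prescribed monthly temperature offsets and
fractional precipitation changes on top, which makes the deterministic part
exactly invertible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .fao56 import extraterrestrial_radiation
from .weather import WeatherSeries

MONTHS = np.arange(1, 13)


def _check12(name: str, values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (12,):
        raise ValueError(f"{name} must have 12 monthly entries, got shape {arr.shape}")
    return arr


@dataclass
class SiteClimatology:
    """Monthly climate statistics driving the stochastic weather generator."""

    site_id: str
    monthly_tmax: Sequence[float]  # deg C
    monthly_tmin: Sequence[float]  # deg C
    monthly_rain: Sequence[float]  # mm total per month
    wet_day_prob: Sequence[float]  # stationary wet-day frequency per month
    wet_persistence: float = 0.65  # P(wet | previous day wet)
    gamma_shape: float = 0.85  # shape of the wet-day amount distribution
    temp_sd: float = 1.6  # day-to-day temperature noise (deg C)
    temp_autocorr: float = 0.6
    latitude: float = 9.0  # deg N
    elevation: float = 2200.0  # m

    def __post_init__(self) -> None:
        self.monthly_tmax = _check12("monthly_tmax", self.monthly_tmax)
        self.monthly_tmin = _check12("monthly_tmin", self.monthly_tmin)
        self.monthly_rain = _check12("monthly_rain", self.monthly_rain)
        self.wet_day_prob = _check12("wet_day_prob", self.wet_day_prob)
        if (self.monthly_rain < 0).any():
            raise ValueError("monthly_rain contains negative totals")
        if ((self.wet_day_prob < 0) | (self.wet_day_prob > 1)).any():
            raise ValueError("wet_day_prob outside [0, 1]")
        if not 0 <= self.wet_persistence <= 1:
            raise ValueError("wet_persistence outside [0, 1]")
        if (self.monthly_tmax < self.monthly_tmin).any():
            raise ValueError("monthly_tmax below monthly_tmin")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")


def generate_weather(clim: SiteClimatology, n_years: int, seed: int,
                     start_year: int = 1981) -> WeatherSeries:
    """Simulate ``n_years`` of daily weather from a monthly climatology.

    Identical (clim, n_years, seed, start_year) always yields an identical
    series.  Monthly rainfall totals, wet-day frequencies and temperature
    means of the output converge to the climatology as ``n_years`` grows.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = np.random.default_rng(seed)
    dates = pd.date_range(f"{start_year}-01-01", f"{start_year + n_years - 1}-12-31",
                          freq="D")
    n = len(dates)
    month = dates.month.to_numpy()
    doy = dates.dayofyear.to_numpy()
    days_in_month = np.array([31, 28.25, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])

    pi = clim.wet_day_prob
    p_ww = np.where(pi > 0, np.minimum(1.0, np.maximum(pi, clim.wet_persistence)), 0.0)
    # wet-after-dry probability from stationarity: pi = p_wd / (1 - p_ww + p_wd)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_wd = np.where(pi < 1, pi * (1 - p_ww) / (1 - pi), 1.0)
    p_wd = np.clip(np.nan_to_num(p_wd), 0.0, 1.0)

    # --- rainfall occurrence (Markov chain) and amounts (gamma) -----------
    wet = np.zeros(n, dtype=bool)
    u = rng.random(n)
    prev = u[0] < pi[month[0] - 1]
    wet[0] = prev
    for i in range(1, n):
        m = month[i] - 1
        p = p_ww[m] if prev else p_wd[m]
        prev = u[i] < p
        wet[i] = prev

    mean_amount = np.zeros(12)
    nz = pi > 0
    mean_amount[nz] = clim.monthly_rain[nz] / (days_in_month[nz] * pi[nz])
    precip = np.zeros(n)
    idx = np.flatnonzero(wet)
    if len(idx):
        shape = clim.gamma_shape
        scale = mean_amount[month[idx] - 1] / shape
        precip[idx] = rng.gamma(shape, scale)

    # --- temperature: monthly mean + AR(1) noise ---------------------------
    eps = rng.normal(0.0, clim.temp_sd, size=(2, n))
    ar = np.empty((2, n))
    rho = clim.temp_autocorr
    ar[:, 0] = eps[:, 0]
    for i in range(1, n):
        ar[:, i] = rho * ar[:, i - 1] + np.sqrt(1 - rho ** 2) * eps[:, i]
    tmax = clim.monthly_tmax[month - 1] + ar[0] - 1.0 * wet  # wet days run cooler
    tmin = clim.monthly_tmin[month - 1] + 0.7 * ar[0] + 0.5 * ar[1]
    tmax = np.maximum(tmax, tmin + 0.5)

    # --- solar radiation: clear-sky curve x cloudiness ---------------------
    ra = np.array([extraterrestrial_radiation(clim.latitude, int(d)) for d in doy])
    cloud = np.where(wet, 0.45, 0.70) + rng.normal(0.0, 0.03, n)
    srad = np.clip(ra * np.clip(cloud, 0.25, 0.78), 1.0, None)

    # --- wind and relative humidity ----------------------------------------
    wind = np.clip(2.0 + rng.normal(0.0, 0.5, n), 0.3, None)
    es = 0.6108 * np.exp(17.27 * tmax / (tmax + 237.3))
    ed = 0.6108 * np.exp(17.27 * tmin / (tmin + 237.3))
    rh = np.clip(100.0 * ed / es + rng.normal(0.0, 5.0, n), 10.0, 100.0)

    df = pd.DataFrame({
        "date": dates, "tmax": tmax, "tmin": tmin, "precip": precip,
        "srad": srad, "wind": wind, "rh": rh,
    })
    return WeatherSeries(clim.site_id, df)


# ---------------------------------------------------------------------------
# Emulated GCM projections
# ---------------------------------------------------------------------------
@dataclass
class GcmDeltaSpec:
    """Prescribed monthly climate-change signal of one emulated GCM."""

    gcm_id: str
    d_tmax: Sequence[float]  # deg C, 12 entries
    d_tmin: Sequence[float]
    d_precip: Sequence[float]  # fractional change, > -1
    noise_scale: float = 0.0  # scale of the historical-run distortions

    def __post_init__(self) -> None:
        self.d_tmax = _check12("d_tmax", self.d_tmax)
        self.d_tmin = _check12("d_tmin", self.d_tmin)
        self.d_precip = _check12("d_precip", self.d_precip)
        if (self.d_precip <= -1).any():
            raise ValueError("d_precip must exceed -1 (cannot remove more than all rain)")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")

    @classmethod
    def uniform(cls, gcm_id: str, d_tmax: float, d_tmin: float, d_precip: float,
                noise_scale: float = 0.0) -> "GcmDeltaSpec":
        return cls(gcm_id, [d_tmax] * 12, [d_tmin] * 12, [d_precip] * 12, noise_scale)


def generate_gcm_series(baseline: WeatherSeries, spec: GcmDeltaSpec,
                        seed: int) -> tuple[WeatherSeries, WeatherSeries]:
    """Emulate one GCM: a distorted historical run and a future run.

    ``historical`` is the baseline plus month-wise distortions with
    ``spec.noise_scale`` amplitude (zero scale reproduces the baseline
    exactly); ``future`` applies the prescribed monthly deltas on top of
    ``historical`` — additively for temperature, multiplicatively for
    precipitation — so that subtracting the deltas from ``future`` recovers
    ``historical`` exactly.
    """
    if len(baseline) < 365:
        raise ValueError("baseline must contain at least one full year")
    rng = np.random.default_rng(seed)
    df = baseline.data
    month = df["date"].dt.month.to_numpy()

    t_bias = rng.normal(0.0, spec.noise_scale, 12)
    p_fact = np.exp(rng.normal(0.0, spec.noise_scale, 12)) if spec.noise_scale > 0 \
        else np.ones(12)

    hist = df.copy()
    hist["tmax"] = df["tmax"].to_numpy() + t_bias[month - 1]
    hist["tmin"] = df["tmin"].to_numpy() + t_bias[month - 1]
    hist["precip"] = df["precip"].to_numpy() * p_fact[month - 1]
    historical = WeatherSeries(f"{baseline.site_id}:{spec.gcm_id}:hist", hist)

    fut = hist.copy()
    fut["tmax"] = hist["tmax"].to_numpy() + spec.d_tmax[month - 1]
    fut["tmin"] = hist["tmin"].to_numpy() + spec.d_tmin[month - 1]
    fut["precip"] = hist["precip"].to_numpy() * (1.0 + spec.d_precip[month - 1])
    future = WeatherSeries(f"{baseline.site_id}:{spec.gcm_id}:future", fut)
    return historical, future


def default_gcm_ensemble(n_gcm: int = 10, seed: int = 0,
                         noise_scale: float = 0.4,
                         d_precip_sign: float = 1.0) -> list[GcmDeltaSpec]:
    """A contrasting set of emulated GCM change signals.

    Warming is drawn around the +1.2 to +1.4 deg C annual-mean signal, with
    minimum-temperature warming slightly above maximum-temperature warming;
    precipitation changes are variable across models and months with an
    overall sign set by ``d_precip_sign`` (site-specific in the study region:
    a slight increase at two sites, a decrease at the third).
    """
    rng = np.random.default_rng(seed)
    specs = []
    for g in range(n_gcm):
        warm = rng.uniform(1.0, 1.7)
        d_tmax = warm + rng.normal(0, 0.25, 12)
        d_tmin = warm + 0.1 + rng.normal(0, 0.25, 12)
        dp = np.clip(d_precip_sign * 0.07 + rng.normal(0, 0.12, 12), -0.6, 0.8)
        specs.append(GcmDeltaSpec(f"gcm{g:02d}", d_tmax, d_tmin, dp,
                                  noise_scale=noise_scale))
    return specs


# ---------------------------------------------------------------------------
# Crop observations
# ---------------------------------------------------------------------------
@dataclass
class CropObservations:
    """Per-season field-book records used for calibration."""

    data: pd.DataFrame  # year, planting_doy, flowering_doy, maturity_doy, grain_yield

    def __post_init__(self) -> None:
        df = self.data.reset_index(drop=True)
        req = ["year", "planting_doy", "flowering_doy", "maturity_doy", "grain_yield"]
        missing = [c for c in req if c not in df.columns]
        if missing:
            raise ValueError(f"observations missing columns: {missing}")
        if not ((df["planting_doy"] < df["flowering_doy"])
                & (df["flowering_doy"] < df["maturity_doy"])).all():
            raise ValueError("require planting < flowering < maturity per season")
        if (df["grain_yield"] < 0).any():
            raise ValueError("negative yield observation")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)


def generate_observations(true_run, noise: tuple[float, float], seed: int) -> CropObservations:
    """Perturb simulated season outcomes into noisy field observations.

    Dates are shifted by rounded Gaussian noise with SD ``noise[0]`` days
    (re-drawn if ordering would be violated); yields by Gaussian noise with
    SD ``noise[1]`` t/ha, re-drawn if negative.
    """
    results = list(true_run)
    if not results:
        raise ValueError("true_run is empty")
    sigma_days, sigma_yield = noise
    if sigma_days < 0 or sigma_yield < 0:
        raise ValueError("noise SDs must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for r in results:
        plant, flow, mat = r.planting_doy, r.flowering_doy, r.maturity_doy
        for _ in range(1000):
            f = flow + int(round(rng.normal(0, sigma_days))) if sigma_days else flow
            m = mat + int(round(rng.normal(0, sigma_days))) if sigma_days else mat
            if plant < f < m:
                break
        else:  # pragma: no cover - astronomically unlikely at sane noise
            f, m = flow, mat
        for _ in range(1000):
            y = r.grain_yield + rng.normal(0, sigma_yield) if sigma_yield else r.grain_yield
            if y >= 0:
                break
        else:  # pragma: no cover
            y = max(0.0, r.grain_yield)
        rows.append({"year": r.year, "planting_doy": plant, "flowering_doy": f,
                     "maturity_doy": m, "grain_yield": y})
    return CropObservations(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Cultivars
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class CultivarInfo:
    name: str
    crop: str  # "wheat" or "maize"
    maturity_group: str
    yield_range: tuple[float, float]  # on-station, t/ha
    days_to_maturity: tuple[int, int]
    observation_years: str

    def __post_init__(self) -> None:
        if self.crop not in ("wheat", "maize"):
            raise ValueError("crop must be 'wheat' or 'maize'")
        lo, hi = self.days_to_maturity
        if not 0 < lo <= hi:
            raise ValueError("days_to_maturity must be a positive interval")

    @property
    def pathway(self) -> str:
        """Photosynthetic pathway follows the crop: wheat C3, maize C4."""
        return "C4" if self.crop == "maize" else "C3"


CULTIVARS = {
    "Wenchi": CultivarInfo("Wenchi", "maize", "intermediate", (8, 12), (160, 200),
                           "2010-2012/2015-2017"),
    "Jibat": CultivarInfo("Jibat", "maize", "intermediate", (8, 12), (160, 200),
                          "2011-2016"),
    "Shina": CultivarInfo("Shina", "wheat", "intermediate", (3, 5), (100, 120),
                          "2001-2006"),
    "Medawolabu": CultivarInfo("Medawolabu", "wheat", "late", (4, 5), (136, 143),
                               "2006-2011"),
}


# ---------------------------------------------------------------------------
# Default site climatologies (tropical highland, unimodal/bimodal rains)
# ---------------------------------------------------------------------------
def default_climatology(site: str) -> SiteClimatology:
    """Synthetic monthly climatologies emulating the three study sites.

    Adet: unimodal summer rains (~1300 mm/yr); Kulumsa: May-October rainy
    season (~900 mm/yr); Sinana: bimodal (March-June and July-October,
    ~900 mm/yr).  Temperatures are cool tropical-highland values.
    """
    presets = {
        "Adet": dict(
            monthly_tmax=[27, 28, 29, 29, 28, 25, 23, 23, 24, 25, 26, 26],
            monthly_tmin=[8, 10, 12, 13, 13, 12, 12, 12, 11, 10, 9, 8],
            monthly_rain=[5, 5, 20, 35, 90, 190, 340, 330, 180, 80, 20, 5],
            wet_day_prob=[0.03, 0.03, 0.08, 0.12, 0.25, 0.55, 0.80, 0.80, 0.55,
                          0.25, 0.08, 0.03],
            latitude=11.3, elevation=2170.0,
        ),
        "Kulumsa": dict(
            monthly_tmax=[23, 24, 25, 25, 25, 23, 21, 21, 22, 22, 22, 22],
            monthly_tmin=[6, 7, 9, 10, 10, 10, 10, 10, 9, 8, 6, 5],
            monthly_rain=[15, 25, 55, 70, 100, 110, 140, 150, 110, 60, 20, 10],
            wet_day_prob=[0.06, 0.10, 0.18, 0.25, 0.35, 0.45, 0.60, 0.62, 0.45,
                          0.20, 0.08, 0.05],
            latitude=8.0, elevation=2200.0,
        ),
        "Sinana": dict(
            monthly_tmax=[24, 25, 25, 24, 24, 23, 21, 21, 22, 22, 22, 23],
            monthly_tmin=[7, 8, 9, 10, 10, 9, 9, 9, 9, 9, 8, 7],
            monthly_rain=[25, 35, 85, 110, 95, 60, 95, 120, 115, 100, 40, 15],
            wet_day_prob=[0.08, 0.12, 0.28, 0.38, 0.32, 0.22, 0.35, 0.42, 0.40,
                          0.32, 0.14, 0.06],
            latitude=7.1, elevation=2460.0,
        ),
    }
    if site not in presets:
        raise ValueError(f"unknown site {site!r}; valid sites: {sorted(presets)}")
    return SiteClimatology(site_id=site, **presets[site])
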