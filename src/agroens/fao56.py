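"""FAO-56 Penman-Monteith reference evapotranspiration (single crop coefficient).

Implements the full daily FAO-56 chain: saturation vapour pressure and its
slope, psychrometric constant from station elevation, extraterrestrial and
clear-sky radiation from latitude and day of year, net shortwave (albedo
0.23) and net longwave radiation, and the combination equation

    ET0 = (0.408 * Delta * (Rn - G) + gamma * 900/(T+273) * u2 * (es - ea))
          / (Delta + gamma * (1 + 0.34 * u2))

with soil heat flux G = 0 at the daily step.  Crop demand is ETc = Kc * ET0
with a single, season-constant crop coefficient.

When neither relative humidity nor dewpoint is available the actual vapour
pressure falls back to the saturation vapour pressure at Tmin (the standard
minimum-temperature dewpoint proxy), with a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

STEFAN_BOLTZMANN = 4.903e-9  # MJ K-4 m-2 day-1
SOLAR_CONSTANT = 0.0820  # MJ m-2 min-1
ALBEDO = 0.23


def svp(t_celsius: float) -> float:
    """Saturation vapour pressure (kPa) at air temperature t (deg C)."""
    return 0.6108 * math.exp(17.27 * t_celsius / (t_celsius + 237.3))


def svp_slope(t_celsius: float) -> float:
    """Slope of the saturation vapour pressure curve (kPa/deg C)."""
    return 4098.0 * svp(t_celsius) / (t_celsius + 237.3) ** 2


def atmospheric_pressure(elevation_m: float) -> float:
    """Barometric pressure (kPa) from elevation."""
    return 101.3 * ((293.0 - 0.0065 * elevation_m) / 293.0) ** 5.26


def psychrometric_constant(elevation_m: float) -> float:
    return 0.000665 * atmospheric_pressure(elevation_m)


def extraterrestrial_radiation(latitude_deg: float, doy: int) -> float:
    """Daily extraterrestrial radiation Ra (MJ m-2 d-1)."""
    phi = math.radians(latitude_deg)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)
    delta = 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)
    x = -math.tan(phi) * math.tan(delta)
    ws = math.acos(min(1.0, max(-1.0, x)))
    return (24.0 * 60.0 / math.pi) * SOLAR_CONSTANT * dr * (
        ws * math.sin(phi) * math.sin(delta)
        + math.cos(phi) * math.cos(delta) * math.sin(ws)
    )


def clear_sky_radiation(latitude_deg: float, doy: int, elevation_m: float) -> float:
    return (0.75 + 2e-5 * elevation_m) * extraterrestrial_radiation(latitude_deg, doy)


@dataclass
class Et0Inputs:
    tmax: float  # deg C
    tmin: float
    srad: float  # MJ m-2 d-1
    wind: float  # m/s at 2 m
    latitude: float  # deg
    elevation: float  # m
    doy: int
    rh: float | None = None  # %
    dewpoint: float | None = None  # deg C
    kc: float = 1.0

    def __post_init__(self) -> None:
        if self.tmax < self.tmin:
            raise ValueError("tmax < tmin")
        if self.srad < 0 or self.wind < 0:
            raise ValueError("srad and wind must be non-negative")
        if self.kc <= 0:
            raise ValueError("Kc must be positive")
        if self.rh is not None and not 0 <= self.rh <= 100:
            raise ValueError("rh outside [0, 100]")


def actual_vapour_pressure(inputs: Et0Inputs, warn: bool = True) -> float:
    """Actual vapour pressure ea (kPa), with the Tmin-dewpoint fallback."""
    if inputs.dewpoint is not None:
        return svp(inputs.dewpoint)
    if inputs.rh is not None:
        es_mean = 0.5 * (svp(inputs.tmax) + svp(inputs.tmin))
        return inputs.rh / 100.0 * es_mean
    if warn:
        warnings.warn(
            "no humidity or dewpoint supplied; using saturation vapour "
            "pressure at Tmin as dewpoint estimate",
            stacklevel=2,
        )
    return svp(inputs.tmin)


def et0_fao56(inputs: Et0Inputs) -> tuple[float, float]:
    """Return (ET0, ETc) in mm/d for one day."""
    tmean = 0.5 * (inputs.tmax + inputs.tmin)
    delta = svp_slope(tmean)
    gamma = psychrometric_constant(inputs.elevation)
    es = 0.5 * (svp(inputs.tmax) + svp(inputs.tmin))
    ea = actual_vapour_pressure(inputs)
    ea = min(ea, es)

    ra = extraterrestrial_radiation(inputs.latitude, inputs.doy)
    rso = (0.75 + 2e-5 * inputs.elevation) * ra
    rns = (1.0 - ALBEDO) * inputs.srad
    rel = 1.0 if rso <= 0 else min(1.0, inputs.srad / rso)
    cloud = max(0.0, 1.35 * rel - 0.35)  # net longwave cannot be a gain
    tmax_k4 = (inputs.tmax + 273.16) ** 4
    tmin_k4 = (inputs.tmin + 273.16) ** 4
    rnl = (
        STEFAN_BOLTZMANN
        * 0.5
        * (tmax_k4 + tmin_k4)
        * (0.34 - 0.14 * math.sqrt(ea))
        * cloud
    )
    rn = rns - rnl

    num = 0.408 * delta * rn + gamma * (900.0 / (tmean + 273.0)) * inputs.wind * (es - ea)
    den = delta + gamma * (1.0 + 0.34 * inputs.wind)
    et0 = max(0.0, num / den)
    return et0, inputs.kc * et0
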