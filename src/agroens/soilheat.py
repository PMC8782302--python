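"""Soil heat transfer: implicit 1-D conduction with three scheme variants.

All three schemes solve vertical heat conduction on the soil grid (extended
to 2 m depth) with moisture-dependent thermal conductivity and volumetric
heat capacity.  They differ in boundary conditions and extra terms:

``leachn_like``
    upper boundary from smoothed weekly-mean air temperature; zero heat flux
    across the lower boundary at 2 m; no convective transport.
``daisy_like``
    soil temperature at zero depth equals the daily air temperature; at the
    bottom an analytic damped-sinusoid solution of the conduction equation
    is prescribed; convective heat transport with the vertical water flux.
``shaw_like``
    as ``daisy_like``, plus a damping of the surface temperature under
    evaporation (latent-heat extraction cools the surface).

Thermal properties follow a simple de Vries-style mixing rule:
``lambda = 0.25 + 1.2 * theta`` W/(m K) and
``C = 2.0e6 * (1 - theta_s) + 4.18e6 * theta`` J/(m3 K).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .soil import SoilGrid

SCHEMES = ("leachn_like", "daisy_like", "shaw_like")
SECONDS_PER_DAY = 86400.0
OMEGA_ANNUAL = 2.0 * np.pi / (365.0 * SECONDS_PER_DAY)  # rad/s


@dataclass
class SoilHeatState:
    temperature: np.ndarray  # deg C per cell of the extended grid
    scheme: str

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown soil heat scheme {self.scheme!r}; valid: {SCHEMES}")
        if not np.all(np.isfinite(self.temperature)):
            raise ValueError("non-finite soil temperature")


def thermal_conductivity(theta: np.ndarray) -> np.ndarray:
    """W/(m K), increasing with water content."""
    return 0.25 + 1.2 * theta


def heat_capacity(theta: np.ndarray, theta_s: np.ndarray) -> np.ndarray:
    """Volumetric heat capacity J/(m3 K) of solids + water."""
    return 2.0e6 * (1.0 - theta_s) + 4.18e6 * theta


class SoilHeatColumn:
    """Heat solver bound to a soil grid, extended to ``depth_cm``.

    Parameters
    ----------
    grid : SoilGrid
        The water/nitrogen grid; the heat grid reuses its cells and pads
        below with cells of the deepest horizon's properties.
    scheme : str
        One of ``leachn_like``, ``daisy_like``, ``shaw_like``.
    t_mean, t_amplitude : float
        Annual mean and amplitude of air temperature, used by the analytic
        bottom boundary of the daisy/shaw schemes.
    phase_doy : float
        Day of year of the air-temperature maximum.
    """

    def __init__(self, grid: SoilGrid, scheme: str, t_mean: float = 18.0,
                 t_amplitude: float = 4.0, phase_doy: float = 105.0,
                 depth_cm: float = 200.0, evap_damping: float = 0.25):
        if scheme not in SCHEMES:
            raise ValueError(f"unknown soil heat scheme {scheme!r}; valid: {SCHEMES}")
        self.grid = grid
        self.scheme = scheme
        self.t_mean = t_mean
        self.t_amplitude = t_amplitude
        self.phase_doy = phase_doy
        self.evap_damping = evap_damping

        z_top = list(grid.z_top)
        z_bot = list(grid.z_bot)
        base = grid.z_bot[-1]
        pad = grid.thickness_cm[-1]
        while base < depth_cm:
            z_top.append(base)
            z_bot.append(min(base + max(pad, 20.0), max(depth_cm, base + 1.0)))
            base = z_bot[-1]
        self.z_top = np.asarray(z_top)
        self.z_bot = np.asarray(z_bot)
        self.n_soil = grid.n_cells  # cells shared with the water grid
        self.n = len(self.z_top)
        self.dz_m = (self.z_bot - self.z_top) / 100.0
        zc = 0.5 * (self.z_top + self.z_bot) / 100.0
        self.z_center_m = zc
        self.dz_half = np.diff(zc)
        ts = grid.hydraulics.theta_s
        self.theta_s_ext = np.concatenate([ts, np.full(self.n - self.n_soil, ts[-1])])

    def initial_state(self, temperature: float | np.ndarray | None = None) -> SoilHeatState:
        t = self.t_mean if temperature is None else temperature
        return SoilHeatState(np.full(self.n, t, dtype=float) if np.isscalar(t)
                             else np.asarray(t, dtype=float).copy(), self.scheme)

    def damping_depth(self, theta: float) -> float:
        """Annual damping depth (m) for a uniform moisture content."""
        lam = float(thermal_conductivity(np.asarray(theta)).item())
        cap = float(heat_capacity(np.asarray(theta),
                                  self.theta_s_ext[-1]).item())
        return float(np.sqrt(2.0 * (lam / cap) / OMEGA_ANNUAL))

    def _bottom_temperature(self, doy: float, theta_bottom: float) -> float:
        d = self.damping_depth(theta_bottom)
        zb = self.z_bot[-1] / 100.0
        phase = 2.0 * np.pi * (doy - self.phase_doy) / 365.0
        return self.t_mean + self.t_amplitude * np.exp(-zb / d) * np.sin(phase - zb / d)

    def step(self, state: SoilHeatState, air_temp: float, weekly_air_temp: float,
             doy: float, theta: np.ndarray, water_flux_mm: float = 0.0,
             evaporation_mm: float = 0.0, dt: float = 1.0) -> SoilHeatState:
        """Advance soil temperature by ``dt`` days.

        ``theta`` is the water-grid moisture profile (length ``n_soil``);
        ``water_flux_mm`` the mean downward water flux through the profile
        (drives convective transport in the daisy/shaw schemes);
        ``evaporation_mm`` today's soil evaporation (shaw surface damping).
        """
        th = np.concatenate([theta, np.full(self.n - self.n_soil, theta[-1])])
        lam = thermal_conductivity(th)
        cap = heat_capacity(th, self.theta_s_ext)
        dt_s = dt * SECONDS_PER_DAY

        if self.scheme == "leachn_like":
            t_surf = weekly_air_temp
        else:
            t_surf = air_temp
            if self.scheme == "shaw_like":
                t_surf = air_temp - self.evap_damping * max(0.0, evaporation_mm)

        n = self.n
        lam_half = 0.5 * (lam[:-1] + lam[1:])
        w_half = lam_half / self.dz_half
        a = np.zeros(n)
        b = cap * self.dz_m / dt_s
        cc = np.zeros(n)
        d = b * state.temperature
        a[1:] -= w_half
        b[1:] += w_half
        cc[:-1] -= w_half
        b[:-1] += w_half
        # surface Dirichlet through the top half cell
        w_top = lam[0] / (0.5 * self.dz_m[0])
        b[0] += w_top
        d[0] += w_top * t_surf
        # bottom boundary
        if self.scheme == "leachn_like":
            pass  # zero flux: nothing to add
        else:
            t_bot = self._bottom_temperature(doy, float(th[-1]))
            w_bot = lam[-1] / (0.5 * self.dz_m[-1])
            b[-1] += w_bot
            d[-1] += w_bot * t_bot

        # convective transport with the water flux (explicit upwind)
        if self.scheme in ("daisy_like", "shaw_like") and water_flux_mm != 0.0:
            q = water_flux_mm / 1000.0 / dt_s  # m/s downward
            cw = 4.18e6
            conv = np.zeros(n)
            t_prev = np.concatenate([[t_surf], state.temperature[:-1]])
            conv = cw * max(q, 0.0) * (t_prev - state.temperature)
            d += conv

        t_new = _solve_tridiag(a, b, cc, d)
        return SoilHeatState(t_new, self.scheme)


def _solve_tridiag(a, b, c, d):
    n = len(d)
    cp = np.empty(n)
    dp = np.empty(n)
    cp[0] = c[0] / b[0]
    dp[0] = d[0] / b[0]
    for i in range(1, n):
        denom = b[i] - a[i] * cp[i - 1]
        cp[i] = c[i] / denom
        dp[i] = (d[i] - a[i] * dp[i - 1]) / denom
    x = np.empty(n)
    x[-1] = dp[-1]
    for i in range(n - 2, -1, -1):
        x[i] = dp[i] - cp[i] * x[i + 1]
    return x


def step_soil_heat(state: SoilHeatState, column: SoilHeatColumn, air_temp: float,
                   weekly_air_temp: float, doy: float, theta: np.ndarray,
                   water_flux_mm: float = 0.0, evaporation_mm: float = 0.0,
                   dt: float = 1.0) -> SoilHeatState:
    """Functional wrapper around :meth:`SoilHeatColumn.step`."""
    if state.scheme != column.scheme:
        raise ValueError("state and column scheme mismatch")
    return column.step(state, air_temp, weekly_air_temp, doy, theta,
                       water_flux_mm, evaporation_mm, dt)
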