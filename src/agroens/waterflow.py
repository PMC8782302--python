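"""Soil water dynamics: cascading tipping bucket and 1-D Richards flow.

Two interchangeable schemes share the same layered grid and the same
step contract (add infiltration, extract soil evaporation and root water
uptake, report drainage below the profile and the other diagnostic fluxes,
all in mm per step):

* **tipping bucket** — each layer retains water up to field capacity; any
  excess cascades instantly to the layer below and leaves the profile as
  drainage at the bottom.  Matric potential is ignored, so upward movement
  (capillary rise) never occurs by construction.
* **Richards** — implicit, mass-conservative finite differences with
  modified-Picard iteration and van Genuchten-Mualem constitutive relations;
  potential gradients drive the flow, so capillary rise is possible.  Free
  drainage (unit gradient) is the default bottom condition; a fixed water
  table is available for contrast experiments.

Soil evaporation is extracted from the cells within the top 15 cm with a
supply-limited reduction (full rate near field capacity, linearly reduced
toward the residual water content); transpiration is extracted per layer,
capped at the plant-available store above wilting point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .soil import HydraulicParams, SoilGrid

EVAP_DEPTH_CM = 15.0


@dataclass
class WaterFluxes:
    """Diagnostic fluxes of one step, mm.

    ``flux_down`` is the downward water flux through the bottom face of each
    cell (mm per step), which drives convective nitrate leaching; its last
    entry equals drainage minus capillary rise.
    """

    infiltration: float = 0.0
    drainage: float = 0.0
    evaporation: float = 0.0
    transpiration: float = 0.0
    runoff: float = 0.0
    capillary_rise: float = 0.0
    flux_down: np.ndarray | None = None


@dataclass
class SoilWaterState:
    theta: np.ndarray  # volumetric water content per cell
    fluxes: WaterFluxes = field(default_factory=WaterFluxes)

    def storage_mm(self, grid: SoilGrid) -> float:
        return float(np.sum(self.theta * grid.thickness_mm))


def initial_water_state(grid: SoilGrid, fraction_of_paw: float = 0.8) -> SoilWaterState:
    """Initial profile at PWP + fraction * (FC - PWP), the annual reset state."""
    hyd = grid.hydraulics
    theta = hyd.theta_pwp + fraction_of_paw * (hyd.theta_fc - hyd.theta_pwp)
    return SoilWaterState(theta.copy())


H_AIR_DRY_CM = 2.0e5  # matric head magnitude at the air-dry surface limit


def air_dry_theta(hyd: HydraulicParams) -> np.ndarray:
    """Water content at the air-dry limit (evaporation cannot pass it)."""
    return vg_theta(np.full(len(hyd.theta_r), -H_AIR_DRY_CM), hyd)


def _extract_evaporation(theta, grid: SoilGrid, demand: float) -> tuple[np.ndarray, float]:
    """Supply-limited soil evaporation from the top cells (<= 15 cm).

    Extraction runs at the full rate near field capacity and is linearly
    reduced toward the air-dry water content, which it never passes (keeps
    the matric heads the Richards solver sees within a sane range).
    """
    hyd = grid.hydraulics
    th_ad = air_dry_theta(hyd)
    taken = 0.0
    remaining = demand
    for i in range(grid.n_cells):
        if grid.z_top[i] >= EVAP_DEPTH_CM or remaining <= 0:
            break
        avail = max(0.0, (theta[i] - th_ad[i]) * grid.thickness_mm[i])
        wet = (theta[i] - th_ad[i]) / max(hyd.theta_fc[i] - th_ad[i], 1e-9)
        rate = min(remaining, avail * min(1.0, max(0.0, wet)))
        theta[i] -= rate / grid.thickness_mm[i]
        taken += rate
        remaining -= rate
    return theta, taken


def _extract_transpiration(theta, grid: SoilGrid, demand: np.ndarray) -> tuple[np.ndarray, float]:
    """Root uptake per cell, capped at plant-available water above PWP."""
    hyd = grid.hydraulics
    taken = 0.0
    for i in range(grid.n_cells):
        if demand[i] <= 0:
            continue
        avail = max(0.0, (theta[i] - hyd.theta_pwp[i]) * grid.thickness_mm[i])
        rate = min(demand[i], avail)
        theta[i] -= rate / grid.thickness_mm[i]
        taken += rate
    return theta, taken


# ---------------------------------------------------------------------------
# Tipping bucket
# ---------------------------------------------------------------------------
def step_tipping_bucket(state: SoilWaterState, grid: SoilGrid,
                        infiltration: float, evap_demand: float,
                        transp_demand: np.ndarray) -> SoilWaterState:
    """One daily step of the cascading-bucket water balance."""
    if infiltration < 0 or evap_demand < 0:
        raise ValueError("water inputs and demands must be >= 0")
    transp_demand = np.asarray(transp_demand, dtype=float)
    if (transp_demand < 0).any():
        raise ValueError("transpiration demands must be >= 0")
    hyd = grid.hydraulics
    theta = state.theta.copy()
    thick = grid.thickness_mm

    # cascade: each bucket retains up to field capacity, excess tips over
    flux_down = np.zeros(grid.n_cells)
    excess = infiltration
    for i in range(grid.n_cells):
        room = max(0.0, (hyd.theta_fc[i] - theta[i]) * thick[i])
        added = min(excess, room)
        theta[i] += added / thick[i]
        excess -= added
        flux_down[i] = excess
    drainage = max(0.0, excess)

    theta, evap = _extract_evaporation(theta, grid, evap_demand)
    theta, transp = _extract_transpiration(theta, grid, transp_demand)

    fluxes = WaterFluxes(infiltration=infiltration, drainage=drainage,
                         evaporation=evap, transpiration=transp,
                         runoff=0.0, capillary_rise=0.0, flux_down=flux_down)
    return SoilWaterState(theta, fluxes)


# ---------------------------------------------------------------------------
# Richards equation (implicit FD, modified Picard)
# ---------------------------------------------------------------------------
def vg_theta(h: np.ndarray, hyd: HydraulicParams) -> np.ndarray:
    """Water content from pressure head (cm, negative unsaturated)."""
    m = 1.0 - 1.0 / hyd.vg_n
    se = np.where(h < 0, (1.0 + (hyd.vg_alpha * np.abs(h)) ** hyd.vg_n) ** (-m), 1.0)
    return hyd.theta_r + se * (hyd.theta_s - hyd.theta_r)


def vg_head(theta: np.ndarray, hyd: HydraulicParams) -> np.ndarray:
    """Pressure head (cm) from water content; saturated cells get h = 0."""
    m = 1.0 - 1.0 / hyd.vg_n
    se = np.clip((theta - hyd.theta_r) / (hyd.theta_s - hyd.theta_r), 1e-9, 1.0)
    h = np.where(se < 1.0,
                 -(se ** (-1.0 / m) - 1.0) ** (1.0 / hyd.vg_n) / hyd.vg_alpha,
                 0.0)
    return h


def vg_capacity(h: np.ndarray, hyd: HydraulicParams) -> np.ndarray:
    """Specific moisture capacity dtheta/dh (1/cm)."""
    m = 1.0 - 1.0 / hyd.vg_n
    ah = hyd.vg_alpha * np.abs(h)
    c = (hyd.theta_s - hyd.theta_r) * hyd.vg_alpha * hyd.vg_n * m \
        * ah ** (hyd.vg_n - 1.0) * (1.0 + ah ** hyd.vg_n) ** (-m - 1.0)
    return np.where(h < 0, c, 1e-8)


def vg_conductivity(h: np.ndarray, hyd: HydraulicParams) -> np.ndarray:
    """Mualem unsaturated conductivity (cm/d)."""
    m = 1.0 - 1.0 / hyd.vg_n
    se = np.where(h < 0, (1.0 + (hyd.vg_alpha * np.abs(h)) ** hyd.vg_n) ** (-m), 1.0)
    se = np.clip(se, 1e-12, 1.0)
    return hyd.ksat * np.sqrt(se) * (1.0 - (1.0 - se ** (1.0 / m)) ** m) ** 2


class RichardsNonConvergence(RuntimeError):
    pass


def _njit(func):
    """numba acceleration when available; the kernel is plain-loop Python."""
    try:
        from numba import njit
        return njit(cache=False)(func)
    except Exception:  # pragma: no cover - numba is normally installed
        return func


@_njit
def _richards_kernel(theta, theta_r, theta_s, ksat, alpha, nvg,
                     dz, dz_half, q_in, dt, bottom_wt, tol, max_picard, dt_min):
    """Sub-daily modified-Picard solve; returns (theta, drainage_cm,
    caprise_cm, flux_down_cm, ok)."""
    n = theta.shape[0]
    drainage = 0.0
    caprise = 0.0
    flux_down = np.zeros(n)
    h = np.empty(n)
    h_new = np.empty(n)
    theta_old = np.empty(n)
    k = np.empty(n)
    a = np.empty(n)
    b = np.empty(n)
    cc = np.empty(n)
    d = np.empty(n)
    cp = np.empty(n)
    dp = np.empty(n)

    t_done = 0.0
    # infiltration into dry soil is strongly nonlinear: start with shorter
    # sub-steps on days with substantial surface input
    sub_dt = dt if q_in < 0.5 else 0.25 * dt
    while t_done < dt - 1e-12:
        if sub_dt > dt - t_done:
            sub_dt = dt - t_done
        for i in range(n):
            theta_old[i] = theta[i]
            # head from water content (inverse van Genuchten)
            m = 1.0 - 1.0 / nvg[i]
            se = (theta[i] - theta_r[i]) / (theta_s[i] - theta_r[i])
            if se < 1e-9:
                se = 1e-9
            if se >= 1.0:
                h[i] = 0.0
            else:
                h[i] = -((se ** (-1.0 / m) - 1.0) ** (1.0 / nvg[i])) / alpha[i]
        converged = False
        for _ in range(max_picard):
            for i in range(n):
                m = 1.0 - 1.0 / nvg[i]
                if h[i] < 0.0:
                    ah = alpha[i] * (-h[i])
                    ahn = ah ** nvg[i]
                    se = (1.0 + ahn) ** (-m)
                    th = theta_r[i] + se * (theta_s[i] - theta_r[i])
                    cmoist = (theta_s[i] - theta_r[i]) * alpha[i] * nvg[i] * m \
                        * ah ** (nvg[i] - 1.0) * (1.0 + ahn) ** (-m - 1.0)
                    if se < 1e-12:
                        se = 1e-12
                    kk = ksat[i] * np.sqrt(se) \
                        * (1.0 - (1.0 - se ** (1.0 / m)) ** m) ** 2
                else:
                    th = theta_s[i]
                    cmoist = 1e-8
                    kk = ksat[i]
                k[i] = kk
                storage = cmoist * dz[i] / sub_dt
                a[i] = 0.0
                cc[i] = 0.0
                b[i] = storage
                d[i] = storage * h[i] - (th - theta_old[i]) * dz[i] / sub_dt
            for i in range(n - 1):
                k_half = 0.5 * (k[i] + k[i + 1])
                w = k_half / dz_half[i]
                # lower face of cell i
                cc[i] -= w
                b[i] += w
                d[i] -= k_half
                # upper face of cell i+1
                a[i + 1] -= w
                b[i + 1] += w
                d[i + 1] += k_half
            d[0] += q_in
            if bottom_wt == 1:
                w = k[n - 1] / (0.5 * dz[n - 1])
                b[n - 1] += w
                d[n - 1] -= k[n - 1]
            else:
                d[n - 1] -= k[n - 1]

            # Thomas algorithm
            cp[0] = cc[0] / b[0]
            dp[0] = d[0] / b[0]
            for i in range(1, n):
                denom = b[i] - a[i] * cp[i - 1]
                cp[i] = cc[i] / denom
                dp[i] = (d[i] - a[i] * dp[i - 1]) / denom
            h_new[n - 1] = dp[n - 1]
            for i in range(n - 2, -1, -1):
                h_new[i] = dp[i] - cp[i] * h_new[i + 1]

            change = 0.0
            finite = True
            for i in range(n):
                diff = abs(h_new[i] - h[i])
                if diff > change:
                    change = diff
                if not np.isfinite(h_new[i]):
                    finite = False
                h[i] = h_new[i]
            if not finite:
                break
            if change < tol:
                converged = True
                break
        if not converged:
            sub_dt *= 0.5
            if sub_dt < dt_min:
                return theta, drainage, caprise, flux_down, False
            continue

        # converged: update state and fluxes from the discrete scheme
        for i in range(n):
            m = 1.0 - 1.0 / nvg[i]
            if h[i] < 0.0:
                ah = alpha[i] * (-h[i])
                se = (1.0 + ah ** nvg[i]) ** (-m)
                th = theta_r[i] + se * (theta_s[i] - theta_r[i])
                if se < 1e-12:
                    se = 1e-12
                k[i] = ksat[i] * np.sqrt(se) \
                    * (1.0 - (1.0 - se ** (1.0 / m)) ** m) ** 2
            else:
                th = theta_s[i]
                k[i] = ksat[i]
            theta[i] = min(max(th, theta_r[i] + 1e-9), theta_s[i])
        for i in range(n - 1):
            k_half = 0.5 * (k[i] + k[i + 1])
            q = -k_half * ((h[i + 1] - h[i]) / dz_half[i] - 1.0)
            flux_down[i] += q * sub_dt
        if bottom_wt == 1:
            w = k[n - 1] / (0.5 * dz[n - 1])
            q_bot = w * h[n - 1] + k[n - 1]
        else:
            q_bot = k[n - 1]
        flux_down[n - 1] += q_bot * sub_dt
        if q_bot >= 0:
            drainage += q_bot * sub_dt
        else:
            caprise += -q_bot * sub_dt
        t_done += sub_dt
        sub_dt = min(sub_dt * 1.5, dt)
    return theta, drainage, caprise, flux_down, True


def _thomas(a, b, c, d):
    """Solve a tridiagonal system (a: sub, b: diag, c: super)."""
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


def step_richards(state: SoilWaterState, grid: SoilGrid,
                  infiltration: float, evap_demand: float,
                  transp_demand: np.ndarray,
                  dt: float = 1.0,
                  bottom: str = "free_drainage",
                  max_picard: int = 15,
                  tol: float = 0.05,
                  dt_min: float = 1e-5) -> SoilWaterState:
    """One step of the implicit mass-conservative Richards solve.

    Sinks (evaporation, uptake) are split off first; the flow solve then
    redistributes water with the surface flux boundary condition, adaptive
    sub-daily stepping and Picard-iteration halving on non-convergence.

    ``bottom`` is ``"free_drainage"`` (unit gradient) or ``"water_table"``
    (saturated boundary at the profile base, h = 0).
    """
    if infiltration < 0 or evap_demand < 0:
        raise ValueError("water inputs and demands must be >= 0")
    transp_demand = np.asarray(transp_demand, dtype=float)
    if (transp_demand < 0).any():
        raise ValueError("transpiration demands must be >= 0")
    if bottom not in ("free_drainage", "water_table"):
        raise ValueError("bottom must be 'free_drainage' or 'water_table'")
    hyd = grid.hydraulics
    theta = state.theta.copy()

    theta, evap = _extract_evaporation(theta, grid, evap_demand)
    theta, transp = _extract_transpiration(theta, grid, transp_demand)

    dz = grid.thickness_cm  # cm
    z = grid.z_center  # cm, positive downward
    dz_half = np.diff(z)
    n = grid.n_cells
    q_surface = infiltration / 10.0 / dt  # mm -> cm/d, applied over the step

    # cap the surface flux at what the top cell plus its conductivity can
    # accept; the remainder is saturation-excess runoff
    h = vg_head(theta, hyd)
    k_top = vg_conductivity(np.array([h[0]]), hyd_slice(hyd, 0))[0]
    cap = k_top + (hyd.theta_s[0] - theta[0]) * dz[0] / dt
    q_in = min(q_surface, cap)
    runoff_mm = max(0.0, (q_surface - q_in) * 10.0 * dt)

    theta, drainage_cm, cap_rise_cm, flux_down_cm, ok = _richards_kernel(
        theta, hyd.theta_r, hyd.theta_s, hyd.ksat, hyd.vg_alpha, hyd.vg_n,
        dz, dz_half, q_in, dt, 1 if bottom == "water_table" else 0,
        tol, max_picard, dt_min)
    if not ok:
        raise RichardsNonConvergence(
            f"Richards solver failed below sub-step floor {dt_min:g} d "
            f"(q_in={q_in:g} cm/d, theta range {theta.min():.3f}-{theta.max():.3f})")

    fluxes = WaterFluxes(infiltration=q_in * 10.0 * dt, drainage=drainage_cm * 10.0,
                         evaporation=evap, transpiration=transp,
                         runoff=runoff_mm, capillary_rise=cap_rise_cm * 10.0,
                         flux_down=flux_down_cm * 10.0)
    return SoilWaterState(theta, fluxes)


def hyd_slice(hyd: HydraulicParams, i: int) -> HydraulicParams:
    """Single-cell view of the hydraulic parameters."""
    return HydraulicParams(*(np.atleast_1d(getattr(hyd, f)[i])
                             for f in ("theta_r", "theta_s", "theta_fc",
                                       "theta_pwp", "ksat", "vg_alpha", "vg_n")))


def step_water(scheme: str, state: SoilWaterState, grid: SoilGrid,
               infiltration: float, evap_demand: float,
               transp_demand: np.ndarray, **kwargs) -> SoilWaterState:
    """Dispatch to the configured water scheme (``tipping`` or ``richards``)."""
    if scheme == "tipping":
        return step_tipping_bucket(state, grid, infiltration, evap_demand, transp_demand)
    if scheme == "richards":
        return step_richards(state, grid, infiltration, evap_demand, transp_demand, **kwargs)
    raise ValueError(f"unknown water scheme {scheme!r}; use 'tipping' or 'richards'")
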