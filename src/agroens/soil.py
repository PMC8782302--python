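"""Layered soil profiles, site fixtures and hydraulic parameterization.

The soil description consists of measured horizon properties (texture, bulk
density, pH, organic carbon, field capacity FC, permanent wilting point PWP,
CEC).  Only those quantities are measured; the hydraulic quantities needed by
the Richards solver (saturated water content, residual water content,
van Genuchten retention parameters, saturated conductivity) are derived from
them by documented pedotransfer rules:

* porosity ``theta_s = 1 - BD / 2.65`` (mineral particle density 2.65 g/cm3),
* residual water content ``theta_r = 0.5 * theta_pwp``,
* van Genuchten ``alpha`` and ``n`` fitted so the retention curve passes
  through (-33 kPa, FC) and (-1500 kPa, PWP),
* ``Ksat`` from the Cosby sand/clay regression.

These are stand-ins: the measured FC/PWP anchor the curve, everything else is
a reproducible convention, not site data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

# capillary head (cm of water) corresponding to the FC / PWP matric potentials
H_FC_CM = 336.6  # 33 kPa
H_PWP_CM = 15296.0  # 1500 kPa


@dataclass(frozen=True)
class SoilHorizon:
    depth_top: float  # cm
    depth_bottom: float  # cm
    silt: float  # %
    clay: float  # %
    bd: float  # bulk density g cm-3
    ph: float
    oc: float  # organic carbon %
    pwp: float  # permanent wilting point vol %
    fc: float  # field capacity vol %
    cec: float  # cmolc kg-1


@dataclass
class SoilProfile:
    site_id: str
    horizons: Sequence[SoilHorizon]

    def __post_init__(self) -> None:
        hs = list(self.horizons)
        if not hs:
            raise ValueError("soil profile needs at least one horizon")
        if hs[0].depth_top != 0:
            raise ValueError("profile must start at 0 cm")
        for a, b in zip(hs, hs[1:]):
            if b.depth_top != a.depth_bottom:
                raise ValueError("horizons must be contiguous and non-overlapping")
        for h in hs:
            if not h.fc > h.pwp:
                raise ValueError(f"FC must exceed PWP in horizon {h.depth_top}-{h.depth_bottom} cm")
            if not (0 < h.bd < 2.65):
                raise ValueError("bulk density outside physical range")
            for name, v in (("silt", h.silt), ("clay", h.clay), ("oc", h.oc),
                            ("pwp", h.pwp), ("fc", h.fc)):
                if not 0 <= v <= 100:
                    raise ValueError(f"{name} outside [0, 100]")
        self.horizons = hs

    @property
    def depth(self) -> float:
        return self.horizons[-1].depth_bottom


# ---------------------------------------------------------------------------
# Site fixtures: measured horizon tables for the three research sites
# (Adet and Sinana: wheat; Kulumsa: maize).  Columns: top, bottom, silt, clay,
# BD, pH, OC, PWP, FC, CEC.
# ---------------------------------------------------------------------------
_SITE_TABLES = {
    "Adet": [
        (0, 5, 31, 40, 1.02, 8.7, 4.17, 31.5, 44.3, 37),
        (5, 15, 31, 41, 1.07, 8.7, 4.10, 31.5, 43.5, 37),
        (15, 30, 31, 44, 1.16, 8.7, 2.50, 31.5, 42.3, 37),
        (30, 60, 28, 46, 1.20, 8.7, 1.90, 31.8, 41.8, 36),
        (60, 100, 28, 47, 1.24, 8.7, 1.50, 31.5, 40.8, 36),
        (100, 125, 27, 47, 1.26, 8.7, 1.00, 31.5, 40.5, 38),
    ],
    "Kulumsa": [
        (0, 5, 28, 42, 1.21, 5.3, 2.60, 31.0, 41.0, 41),
        (5, 15, 28, 44, 1.23, 5.3, 2.40, 31.0, 41.0, 40),
        (15, 30, 28, 46, 1.35, 5.3, 1.40, 31.0, 39.0, 40),
        (30, 60, 25, 47, 1.40, 5.3, 1.00, 31.0, 38.2, 41),
        (60, 100, 25, 47, 1.45, 5.3, 0.60, 30.7, 37.7, 40),
        (100, 150, 26, 45, 1.47, 5.3, 0.50, 30.0, 37.0, 41),
    ],
    "Sinana": [
        (0, 5, 26, 39, 1.12, 6.7, 3.30, 31.5, 42.5, 45),
        (5, 15, 26, 41, 1.18, 6.7, 2.90, 32.0, 42.0, 46),
        (15, 30, 25, 45, 1.26, 6.7, 2.10, 32.0, 41.0, 46),
        (30, 60, 24, 47, 1.30, 6.7, 1.60, 32.5, 40.5, 47),
        (60, 100, 24, 47, 1.39, 6.7, 1.40, 32.0, 39.0, 46),
        (100, 145, 24, 47, 1.45, 6.7, 1.20, 31.5, 37.5, 45),
    ],
}


def load_soil_fixture(site: str) -> SoilProfile:
    """Return the measured soil profile for one of the three study sites."""
    if site not in _SITE_TABLES:
        raise ValueError(f"unknown site {site!r}; valid sites: {sorted(_SITE_TABLES)}")
    horizons = [SoilHorizon(*row) for row in _SITE_TABLES[site]]
    return SoilProfile(site, horizons)


#: text-export column names (matching the site-table convention)
SOIL_COLUMNS = ["site", "depth_top", "depth_bottom", "silt", "clay", "BD",
                "pH", "OC", "PWP", "FC", "CEC"]


def soil_to_csv(profile: SoilProfile, path) -> None:
    """Write a profile as delimited text, one row per horizon."""
    import pandas as pd
    rows = [{"site": profile.site_id, "depth_top": h.depth_top,
             "depth_bottom": h.depth_bottom, "silt": h.silt, "clay": h.clay,
             "BD": h.bd, "pH": h.ph, "OC": h.oc, "PWP": h.pwp, "FC": h.fc,
             "CEC": h.cec} for h in profile.horizons]
    pd.DataFrame(rows)[SOIL_COLUMNS].to_csv(path, index=False)


def soil_from_csv(path) -> SoilProfile:
    """Read a profile written by :func:`soil_to_csv`."""
    import pandas as pd
    df = pd.read_csv(path)
    missing = [c for c in SOIL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"soil file missing columns: {missing}")
    horizons = [SoilHorizon(r.depth_top, r.depth_bottom, r.silt, r.clay, r.BD,
                            r.pH, r.OC, r.PWP, r.FC, r.CEC)
                for r in df.itertuples()]
    return SoilProfile(str(df["site"].iloc[0]), horizons)


def soil_state_frame(grid: "SoilGrid", theta, temperature=None):
    """Tidy snapshot of the soil state (layer, depth, theta, temperature)."""
    import pandas as pd
    data = {"layer": np.arange(grid.n_cells),
            "depth_top_cm": grid.z_top, "depth_bottom_cm": grid.z_bot,
            "theta": np.asarray(theta)[:grid.n_cells]}
    if temperature is not None:
        data["temperature_c"] = np.asarray(temperature)[:grid.n_cells]
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Hydraulic parameterization
# ---------------------------------------------------------------------------
@dataclass
class HydraulicParams:
    """Per-cell hydraulic parameters on the computational grid.

    All water contents are volumetric fractions; ``ksat`` is cm/d.
    """

    theta_r: np.ndarray
    theta_s: np.ndarray
    theta_fc: np.ndarray
    theta_pwp: np.ndarray
    ksat: np.ndarray
    vg_alpha: np.ndarray  # 1/cm
    vg_n: np.ndarray

    def __post_init__(self) -> None:
        ok = (self.theta_r < self.theta_pwp) & (self.theta_pwp < self.theta_fc) \
            & (self.theta_fc < self.theta_s)
        if not ok.all():
            raise ValueError("require theta_r < theta_pwp < theta_fc < theta_s per cell")
        if (self.ksat <= 0).any():
            raise ValueError("Ksat must be positive")
        if (self.vg_n <= 1).any():
            raise ValueError("van Genuchten n must exceed 1")


def _fit_van_genuchten(theta_r, theta_s, theta_fc, theta_pwp):
    """Fit (alpha, n) so Se(h) passes through the FC and PWP anchor points."""
    se_fc = (theta_fc - theta_r) / (theta_s - theta_r)
    se_pwp = (theta_pwp - theta_r) / (theta_s - theta_r)

    def alpha_for(n, se, h):
        m = 1.0 - 1.0 / n
        return (se ** (-1.0 / m) - 1.0) ** (1.0 / n) / h

    def resid(n):
        a = alpha_for(n, se_fc, H_FC_CM)
        m = 1.0 - 1.0 / n
        se2 = (1.0 + (a * H_PWP_CM) ** n) ** (-m)
        return se2 - se_pwp

    # n in a physically sensible band for clayey soils
    lo, hi = 1.05, 3.0
    try:
        n = brentq(resid, lo, hi, xtol=1e-10)
    except ValueError:
        # no sign change: pick the end with the smaller residual
        n = lo if abs(resid(lo)) < abs(resid(hi)) else hi
    return alpha_for(n, se_fc, H_FC_CM), n


def _cosby_ksat(silt: float, clay: float) -> float:
    """Saturated conductivity (cm/d) from the Cosby sand/clay regression."""
    sand = max(100.0 - silt - clay, 0.0)
    log_in_hr = -0.6 + 0.0126 * sand - 0.0064 * clay
    return 10.0 ** log_in_hr * 2.54 * 24.0


@dataclass
class SoilGrid:
    """Computational grid shared by the water, heat and nitrogen solvers.

    Horizons are subdivided into cells of at most ``max_cell_cm`` thickness;
    each cell carries the properties of its parent horizon.
    """

    profile: SoilProfile
    z_top: np.ndarray  # cm
    z_bot: np.ndarray  # cm
    horizon_index: np.ndarray
    hydraulics: HydraulicParams
    oc: np.ndarray  # %
    bd: np.ndarray  # g cm-3

    @property
    def n_cells(self) -> int:
        return len(self.z_top)

    @property
    def thickness_cm(self) -> np.ndarray:
        return self.z_bot - self.z_top

    @property
    def thickness_mm(self) -> np.ndarray:
        return 10.0 * (self.z_bot - self.z_top)

    @property
    def z_center(self) -> np.ndarray:
        return 0.5 * (self.z_top + self.z_bot)


def make_grid(profile: SoilProfile, max_cell_cm: float = 15.0) -> SoilGrid:
    z_top, z_bot, hidx = [], [], []
    for i, h in enumerate(profile.horizons):
        span = h.depth_bottom - h.depth_top
        n = max(1, int(np.ceil(span / max_cell_cm)))
        edges = np.linspace(h.depth_top, h.depth_bottom, n + 1)
        z_top.extend(edges[:-1])
        z_bot.extend(edges[1:])
        hidx.extend([i] * n)
    z_top = np.asarray(z_top)
    z_bot = np.asarray(z_bot)
    hidx = np.asarray(hidx, dtype=int)

    hs = profile.horizons
    fc = np.array([hs[i].fc / 100.0 for i in hidx])
    pwp = np.array([hs[i].pwp / 100.0 for i in hidx])
    bd = np.array([hs[i].bd for i in hidx])
    theta_s = 1.0 - bd / 2.65
    # porosity must clear FC by a margin for the retention fit to be sane
    theta_s = np.maximum(theta_s, fc + 0.02)
    theta_r = 0.5 * pwp

    alpha = np.empty(len(hidx))
    n_vg = np.empty(len(hidx))
    cache: dict[int, tuple[float, float]] = {}
    for j, i in enumerate(hidx):
        if i not in cache:
            cache[i] = _fit_van_genuchten(theta_r[j], theta_s[j], fc[j], pwp[j])
        alpha[j], n_vg[j] = cache[i]

    ksat = np.array([_cosby_ksat(hs[i].silt, hs[i].clay) for i in hidx])
    hyd = HydraulicParams(theta_r, theta_s, fc, pwp, ksat, alpha, n_vg)
    oc = np.array([hs[i].oc for i in hidx])
    return SoilGrid(profile, z_top, z_bot, hidx, hyd, oc, bd)
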