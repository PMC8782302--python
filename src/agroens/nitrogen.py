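"""Soil organic matter turnover and mineral nitrogen bookkeeping.

Two pool structures are available for the factorial ensemble:

* ``soiln3`` — three pools (humus, litter, manure) with distinct first-order
  turnover rates; litter and manure decay is partly humified, the rest
  respired.
* ``daisy6`` — six pools: added organic matter (fast/slow), soil microbial
  biomass (fast/slow) and native soil organic matter (fast/slow), with
  decayed carbon routed between them at fixed utilization efficiencies.

Both share the same engine: each pool decays first order at
``k * f_T(temperature) * f_theta(moisture)``; decayed C is routed according
to a transfer-fraction matrix whose rows (plus the respired CO2 fraction)
sum to one; nitrogen follows carbon via fixed pool C:N ratios, and net
mineralization is the released minus immobilized N (it may be negative).
Rate constants, C:N ratios and humification fractions are documented
defaults from the two parent-model traditions; the ensemble contrast needs
two distinct but defensible parameterizations, not ports.

Mineral N is tracked as NO3-N and NH4-N per layer with fertilizer inputs,
first-order nitrification, demand-capped crop uptake and convective nitrate
leaching assuming full mixing within each layer.  Denitrification and
volatilization are omitted, which keeps the N balance exactly auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .soil import SoilGrid

VARIANTS = ("soiln3", "daisy6")

_SOILN3 = {
    "pools": ("humus", "litter", "manure"),
    "k": np.array([7e-5, 0.035, 0.012]),  # 1/d
    "cn": np.array([10.0, 25.0, 15.0]),
    # rows: source pool; columns: destination; remainder respired as CO2
    "transfer": np.array([
        [0.00, 0.00, 0.00],   # humus -> (fully respired)
        [0.20, 0.00, 0.00],   # litter -> humus (humification 0.2)
        [0.25, 0.00, 0.00],   # manure -> humus
    ]),
    "init_fractions": np.array([0.95, 0.04, 0.01]),
    "litter_pool": "litter",
}

_DAISY6 = {
    "pools": ("aom_fast", "aom_slow", "smb_fast", "smb_slow", "som_fast", "som_slow"),
    "k": np.array([0.05, 0.005, 0.01, 1e-4, 1.4e-4, 2.7e-6]),
    "cn": np.array([25.0, 25.0, 6.7, 6.7, 11.0, 11.0]),
    "transfer": np.array([
        # aom_f aom_s smb_f smb_s som_f som_s
        [0.0, 0.0, 0.60, 0.00, 0.0, 0.0],   # aom_fast -> smb_fast
        [0.0, 0.0, 0.00, 0.60, 0.0, 0.0],   # aom_slow -> smb_slow
        [0.0, 0.0, 0.00, 0.00, 0.40, 0.0],  # smb_fast death -> som_fast
        [0.0, 0.0, 0.00, 0.00, 0.00, 0.40], # smb_slow death -> som_slow
        [0.0, 0.0, 0.50, 0.00, 0.0, 0.0],   # som_fast utilized by smb_fast
        [0.0, 0.0, 0.00, 0.50, 0.0, 0.0],   # som_slow utilized by smb_slow
    ]),
    "init_fractions": np.array([0.02, 0.06, 0.01, 0.02, 0.40, 0.49]),
    "litter_pool": "aom_fast",
}

_DEFAULTS = {"soiln3": _SOILN3, "daisy6": _DAISY6}


@dataclass
class SomPools:
    """Per-layer, per-pool soil organic carbon stocks with fixed C:N ratios."""

    variant: str
    pool_names: tuple[str, ...]
    c: np.ndarray  # (n_layers, n_pools) kg C/ha
    cn: np.ndarray  # (n_pools,)
    k: np.ndarray  # (n_pools,) 1/d
    transfer: np.ndarray  # (n_pools, n_pools)
    litter_pool: int = 1

    def __post_init__(self) -> None:
        if (self.c < 0).any():
            raise ValueError("negative pool carbon")
        if (self.k < 0).any():
            raise ValueError("negative rate constant")
        out = self.transfer.sum(axis=1)
        if (out > 1.0 + 1e-12).any():
            raise ValueError("transfer fractions exceed 1; respired fraction would be negative")

    @property
    def respired_fraction(self) -> np.ndarray:
        return 1.0 - self.transfer.sum(axis=1)

    @property
    def n(self) -> np.ndarray:
        """Organic N per layer and pool (kg N/ha)."""
        return self.c / self.cn

    @property
    def total_c(self) -> float:
        return float(self.c.sum())

    @property
    def total_n(self) -> float:
        return float(self.n.sum())

    def add_residue(self, layer: int, c_kg: float) -> None:
        """Route crop residue carbon into the variant's litter input pool."""
        if c_kg < 0:
            raise ValueError("residue carbon must be >= 0")
        self.c[layer, self.litter_pool] += c_kg


def init_som_from_profile(grid: SoilGrid, variant: str) -> SomPools:
    """Partition measured organic carbon into the variant's pools.

    Total C per layer is OC% x bulk density x thickness (the only measured C
    input); the split among pools uses the variant's documented default
    fractions and conserves total C exactly.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown SOM variant {variant!r}; valid: {VARIANTS}")
    cfg = _DEFAULTS[variant]
    # kg C/ha = OC%/100 * BD (g/cm3) * thickness (cm) * 1e5
    layer_c = grid.oc / 100.0 * grid.bd * grid.thickness_cm * 1.0e5
    c = np.outer(layer_c, cfg["init_fractions"])
    return SomPools(variant, cfg["pools"], c, cfg["cn"].copy(), cfg["k"].copy(),
                    cfg["transfer"].copy(),
                    litter_pool=cfg["pools"].index(cfg["litter_pool"]))


def temperature_modifier(soil_temp: np.ndarray) -> np.ndarray:
    """Q10 = 2 response centred at the 25 deg C reference, capped at 1.2."""
    return np.clip(2.0 ** ((np.asarray(soil_temp, dtype=float) - 25.0) / 10.0),
                   0.0, 1.2)


def moisture_modifier(theta: np.ndarray, theta_r: np.ndarray, theta_fc: np.ndarray,
                      theta_s: np.ndarray) -> np.ndarray:
    """Piecewise-linear moisture response: 1 at field capacity, reduced when
    dry or saturated."""
    theta = np.asarray(theta, dtype=float)
    rising = np.clip((theta - theta_r) / np.maximum(theta_fc - theta_r, 1e-9), 0.0, 1.0)
    wetside = np.clip(1.0 - 0.4 * (theta - theta_fc)
                      / np.maximum(theta_s - theta_fc, 1e-9), 0.6, 1.0)
    return np.where(theta <= theta_fc, rising, wetside)


def step_som_turnover(pools: SomPools, soil_temp: np.ndarray, f_moist: np.ndarray,
                      dt: float = 1.0) -> tuple[SomPools, np.ndarray]:
    """First-order decay of every pool with temperature/moisture modifiers.

    Returns the new pools and per-layer net mineralization (kg N/ha, may be
    negative = immobilization).  Carbon leaves only as respired CO2 and
    organic N changes by exactly minus the net mineralization.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    f_t = temperature_modifier(soil_temp)
    f = (f_t * np.asarray(f_moist, dtype=float))[:, None]  # (layers, 1)
    decay = pools.c * (1.0 - np.exp(-pools.k[None, :] * f * dt))  # kg C
    incoming = decay @ pools.transfer  # (layers, pools)
    c_new = pools.c - decay + incoming
    n_released = (decay / pools.cn[None, :]).sum(axis=1)
    n_immobilized = (incoming / pools.cn[None, :]).sum(axis=1)
    net_min = n_released - n_immobilized
    new = SomPools(pools.variant, pools.pool_names, c_new, pools.cn, pools.k,
                   pools.transfer, pools.litter_pool)
    return new, net_min


# ---------------------------------------------------------------------------
# Mineral nitrogen
# ---------------------------------------------------------------------------
NITRIFICATION_RATE = 0.2  # 1/d


@dataclass
class NFluxes:
    """Per-step N diagnostics, kg N/ha."""

    net_mineralization: float = 0.0
    fertilizer: float = 0.0
    uptake: float = 0.0
    leached: float = 0.0
    immobilization_deficit: float = 0.0  # demanded immobilization not met


@dataclass
class MineralNState:
    no3: np.ndarray  # kg N/ha per layer
    nh4: np.ndarray
    fluxes: NFluxes = field(default_factory=NFluxes)

    def __post_init__(self) -> None:
        if (self.no3 < -1e-9).any() or (self.nh4 < -1e-9).any():
            raise ValueError("negative mineral N stock")

    @property
    def total(self) -> float:
        return float(self.no3.sum() + self.nh4.sum())


def initial_mineral_n(grid: SoilGrid, profile_no3: float = 10.0) -> MineralNState:
    """Annual-reset mineral N: ``profile_no3`` kg NO3-N/ha spread over the
    profile by thickness, with a small NH4 complement."""
    w = grid.thickness_mm / grid.thickness_mm.sum()
    return MineralNState(no3=profile_no3 * w, nh4=0.2 * profile_no3 * w)


def step_mineral_n(state: MineralNState, grid: SoilGrid,
                   mineralization: np.ndarray,
                   fertilizer_n: float,
                   uptake_demand: np.ndarray,
                   flux_down_mm: np.ndarray,
                   theta: np.ndarray,
                   dt: float = 1.0) -> MineralNState:
    """Advance the mineral N balance one step.

    Order of operations: fertilizer to the surface layer; net mineralization
    (negative values drawn from NH4 then NO3, capped at availability);
    first-order nitrification; uptake capped per layer at stock; convective
    NO3 leaching with the per-layer downward water flux, full mixing within
    a layer (``leached_i = NO3_i * min(1, q_i / stored water_i)``).
    """
    mineralization = np.asarray(mineralization, dtype=float)
    uptake_demand = np.asarray(uptake_demand, dtype=float)
    # upward (negative) water fluxes carry no nitrate here: convective
    # transport is downward-only, so they are clipped to zero
    flux_down_mm = np.maximum(np.asarray(flux_down_mm, dtype=float), 0.0)
    if fertilizer_n < 0 or (uptake_demand < 0).any():
        raise ValueError("fertilizer and uptake demands must be >= 0")
    no3 = state.no3.copy()
    nh4 = state.nh4.copy()
    n = len(no3)

    nh4[0] += fertilizer_n

    applied_min = 0.0
    deficit = 0.0
    for i in range(n):
        m = mineralization[i]
        if m >= 0:
            nh4[i] += m
            applied_min += m
        else:
            need = -m
            from_nh4 = min(need, nh4[i])
            nh4[i] -= from_nh4
            need -= from_nh4
            from_no3 = min(need, no3[i])
            no3[i] -= from_no3
            need -= from_no3
            applied_min -= (from_nh4 + from_no3)
            deficit += need

    nitrified = nh4 * (1.0 - np.exp(-NITRIFICATION_RATE * dt))
    nh4 -= nitrified
    no3 += nitrified

    uptake = 0.0
    for i in range(n):
        d = uptake_demand[i]
        if d <= 0:
            continue
        from_no3 = min(d, no3[i])
        no3[i] -= from_no3
        d -= from_no3
        from_nh4 = min(d, nh4[i])
        nh4[i] -= from_nh4
        uptake += from_no3 + from_nh4

    # convective leaching, cascading downward with full mixing per layer
    stored = theta * grid.thickness_mm
    carried = 0.0
    for i in range(n):
        no3[i] += carried
        q = max(0.0, flux_down_mm[i])
        frac = min(1.0, q / stored[i]) if stored[i] > 0 else (1.0 if q > 0 else 0.0)
        carried = no3[i] * frac
        no3[i] -= carried
    leached = carried

    fluxes = NFluxes(net_mineralization=applied_min, fertilizer=fertilizer_n,
                     uptake=uptake, leached=leached,
                     immobilization_deficit=deficit)
    return MineralNState(no3, nh4, fluxes)
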