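"""Generic daily crop simulator with four switchable structural variants.

One shared daily core (thermal-time phenology, canopy light interception,
assimilation, partitioning, leaf-area dynamics, senescence, water/N stress,
grain filling with an explicit grain-N pool) is specialized by a
:class:`GrowthVariant` switch set into four contrasting structures spanning
the common crop-modelling families:

===========  ============  =========  ============  ==================  ============
variant      canopy        leaf Ci    partitioning  senescence drivers  roots
===========  ============  =========  ============  ==================  ============
ceres_like   big leaf      none       priority      age/drought/N       dynamic
sucros_like  3-layer       const      fixed         age/shade/temp      exponential
spass_like   5-layer       const      fixed         age/shade/temp/N    dynamic
gecros_like  two-leaf      coupled    optimized     N translocation     uniform
===========  ============  =========  ============  ==================  ============

These are structural stand-ins built from the published contrasts between
the parent model families, not ports of their code.  Carbon and nitrogen are
book-kept exactly: the daily change in total live biomass equals net
assimilation minus senesced losses, and crop N equals cumulative soil uptake
minus N in senesced tissue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

VARIANT_IDS = ("ceres_like", "sucros_like", "spass_like", "gecros_like")

STAGE_PRESOW = "presow"
STAGE_VEGETATIVE = "vegetative"
STAGE_GRAINFILL = "grainfill"
STAGE_MATURE = "mature"


@dataclass(frozen=True)
class GrowthVariant:
    """Structural switch set defining one crop-model variant."""

    id: str
    canopy: str  # big_leaf | multilayer3 | multilayer5 | two_leaf
    ci_scheme: str  # none | constant_ci_ca | coupled
    partitioning: str  # priority | fixed | optimized
    senescence: tuple[str, ...]
    root_distribution: str  # dynamic | exponential | uniform


VARIANTS: dict[str, GrowthVariant] = {
    "ceres_like": GrowthVariant("ceres_like", "big_leaf", "none", "priority",
                                ("age", "drought", "nitrogen"), "dynamic"),
    "sucros_like": GrowthVariant("sucros_like", "multilayer3", "constant_ci_ca",
                                 "fixed", ("age", "self_shading", "temperature"),
                                 "exponential"),
    "spass_like": GrowthVariant("spass_like", "multilayer5", "constant_ci_ca",
                                "fixed", ("age", "self_shading", "temperature",
                                          "nitrogen"), "dynamic"),
    "gecros_like": GrowthVariant("gecros_like", "two_leaf", "coupled", "optimized",
                                 ("n_translocation",), "uniform"),
}


@dataclass
class GenotypeParams:
    """Cultivar parameters shared by all variants.

    Thermal time is accumulated as max(0, Tmean - t_base) degree-days;
    flowering and maturity occur at the configured thresholds.
    """

    t_base: float = 0.0  # deg C
    tt_flowering: float = 900.0  # deg C d
    tt_maturity: float = 1600.0
    pathway: str = "C3"
    rue: float = 1.5  # g DM per MJ intercepted global radiation (ceres)
    amax: float = 38.0  # g CH2O m-2 leaf d-1 light-saturated rate (others)
    lue: float = 4.0  # g CH2O MJ-1 PAR initial light-use slope
    k_ext: float = 0.60
    sla: float = 0.022  # m2 leaf per g leaf
    max_root_depth: float = 120.0  # cm
    root_growth_rate: float = 1.5  # cm/d
    base_root_frac: float = 0.25
    grain_frac_max: float = 0.75  # grainfill allocation ceiling
    leaf_n_conc: float = 0.035  # target kg N / kg leaf
    stem_n_conc: float = 0.010
    root_n_conc: float = 0.010
    grain_n_conc: float = 0.020
    co2_boost: float = 0.25  # assimilation boost at 720 ppm (C3)
    co2_boost_c4: float = 0.04  # boost at the 450 ppm saturation (C4)
    t_assim: tuple[float, float, float, float] = (0.0, 12.0, 22.0, 35.0)
    initial_biomass: float = 40.0  # kg/ha at emergence
    water_extraction: float = 0.09  # fraction of PAW extractable per day

    def __post_init__(self) -> None:
        if not 0 < self.tt_flowering < self.tt_maturity:
            raise ValueError("require 0 < tt_flowering < tt_maturity")
        if not 0 < self.k_ext <= 1.2:
            raise ValueError("k_ext must lie in (0, 1.2]")
        if self.pathway not in ("C3", "C4"):
            raise ValueError("pathway must be 'C3' or 'C4'")


def wheat_genotype(**overrides) -> GenotypeParams:
    """Cool-season C3 default: assimilation optimum 11-20 deg C, declining
    above (wheat is heat-sensitive), ~110 days to maturity at a 16-17 deg C
    highland season."""
    base = dict(t_base=0.0, tt_flowering=1000.0, tt_maturity=1800.0, pathway="C3",
                rue=1.45, amax=36.0, sla=0.022, grain_n_conc=0.022,
                t_assim=(0.0, 11.0, 20.0, 32.0), max_root_depth=110.0)
    base.update(overrides)
    return GenotypeParams(**base)


def maize_genotype(**overrides) -> GenotypeParams:
    """Warm-season C4 default: broad warm optimum, ~170-190 days to maturity
    in the cool highlands (intermediate maturity group)."""
    base = dict(t_base=8.0, tt_flowering=700.0, tt_maturity=1350.0, pathway="C4",
                rue=1.85, amax=48.0, sla=0.018, grain_n_conc=0.014,
                t_assim=(8.0, 18.0, 33.0, 44.0), max_root_depth=130.0,
                grain_frac_max=0.78)
    base.update(overrides)
    return GenotypeParams(**base)


@dataclass
class CropState:
    tt: float = 0.0
    stage: str = STAGE_PRESOW
    lai: float = 0.0
    leaf: float = 0.0  # kg DM/ha
    stem: float = 0.0
    root: float = 0.0
    grain: float = 0.0
    n_leaf: float = 0.0  # kg N/ha
    n_stem: float = 0.0
    n_root: float = 0.0
    n_grain: float = 0.0
    root_depth: float = 0.0  # cm
    planting_doy: int | None = None
    flowering_doy: int | None = None
    maturity_doy: int | None = None
    cum_assimilation: float = 0.0  # kg DM/ha
    cum_senesced: float = 0.0
    cum_n_uptake: float = 0.0
    cum_n_senesced: float = 0.0
    senesced_today: float = 0.0
    senesced_n_today: float = 0.0

    @property
    def biomass(self) -> float:
        return self.leaf + self.stem + self.root + self.grain

    @property
    def above_ground(self) -> float:
        return self.leaf + self.stem + self.grain

    @property
    def n_crop(self) -> float:
        return self.n_leaf + self.n_stem + self.n_root + self.n_grain


def sow(state: CropState, doy: int, params: GenotypeParams) -> CropState:
    """Emergence: seed the biomass pools and open the vegetative stage."""
    b0 = params.initial_biomass
    leaf, root = 0.6 * b0, 0.4 * b0
    return replace(state, stage=STAGE_VEGETATIVE, planting_doy=doy,
                   leaf=leaf, root=root, lai=leaf / 10.0 * params.sla,
                   n_leaf=leaf * params.leaf_n_conc,
                   n_root=root * params.root_n_conc,
                   root_depth=10.0)


# ---------------------------------------------------------------------------
# Phenology
# ---------------------------------------------------------------------------
def step_phenology(state: CropState, tmean: float, params: GenotypeParams,
                   doy: int | None = None) -> CropState:
    """Accumulate thermal time and flip stages at the configured thresholds."""
    if state.stage in (STAGE_PRESOW, STAGE_MATURE):
        return state
    tt = state.tt + max(0.0, tmean - params.t_base)
    stage = state.stage
    flowering = state.flowering_doy
    maturity = state.maturity_doy
    if stage == STAGE_VEGETATIVE and tt >= params.tt_flowering:
        stage = STAGE_GRAINFILL
        flowering = doy
    if tt >= params.tt_maturity:
        stage = STAGE_MATURE
        maturity = doy
    return replace(state, tt=tt, stage=stage, flowering_doy=flowering,
                   maturity_doy=maturity)


# ---------------------------------------------------------------------------
# Canopy light interception
# ---------------------------------------------------------------------------
def intercepted_fraction(lai: float, k: float, scheme: str = "big_leaf") -> float:
    """Fraction of incoming radiation intercepted by the canopy.

    All schemes agree in the total for a uniform canopy (the multilayer sums
    telescope to the big-leaf exponential; the two-leaf split partitions the
    same total into sunlit and shaded fractions).
    """
    if lai < 0:
        raise ValueError("LAI must be >= 0")
    if scheme in ("big_leaf", "two_leaf"):
        return 1.0 - math.exp(-k * lai)
    if scheme == "multilayer3":
        return sum(layer_interception(lai, k, 3))
    if scheme == "multilayer5":
        return sum(layer_interception(lai, k, 5))
    raise ValueError(f"unknown canopy scheme {scheme!r}")


def layer_interception(lai: float, k: float, n_layers: int) -> list[float]:
    """Beer-law interception per canopy layer of equal LAI."""
    bounds = np.linspace(0.0, lai, n_layers + 1)
    trans = np.exp(-k * bounds)
    return list(trans[:-1] - trans[1:])


def sunlit_shaded_split(lai: float, k: float) -> tuple[float, float]:
    """Sunlit / shaded interception split of the two-leaf scheme."""
    total = 1.0 - math.exp(-k * lai)
    if lai <= 0:
        return 0.0, 0.0
    sunlit_lai = (1.0 - math.exp(-k * lai)) / k
    frac_sun = min(1.0, sunlit_lai / lai)
    return total * frac_sun, total * (1.0 - frac_sun)


# ---------------------------------------------------------------------------
# CO2 response
# ---------------------------------------------------------------------------
CO2_REFERENCE = 360.0
C4_SATURATION = 450.0


def co2_response(co2: float, pathway: str, params: GenotypeParams | None = None) -> float:
    """Assimilation multiplier relative to the 360 ppm reference.

    C3: saturating Michaelis-type increase calibrated so 360 -> 720 ppm gives
    the configured boost.  C4: small linear increase saturating at 450 ppm,
    beyond which there is no further response.
    """
    if co2 <= 0:
        raise ValueError("co2 must be positive")
    boost = params.co2_boost if params else 0.25
    boost4 = params.co2_boost_c4 if params else 0.04
    if pathway == "C4":
        c = min(co2, C4_SATURATION)
        mult = 1.0 + boost4 * (c - CO2_REFERENCE) / (C4_SATURATION - CO2_REFERENCE)
        return max(0.5, mult)
    # Michaelis constant solved so a 360 -> 720 ppm doubling gives the
    # configured boost:  m(C) = C/(C+K), m(720)/m(360) = 1 + boost
    b = 1.0 + boost
    km = 720.0 * 360.0 * boost / (720.0 - b * 360.0) if 720.0 - b * 360.0 > 0 else 1e9
    return (co2 / (co2 + km)) / (CO2_REFERENCE / (CO2_REFERENCE + km))


def temperature_factor(tmean: float, t_assim: tuple[float, float, float, float]) -> float:
    """Trapezoidal temperature response of assimilation, in [0, 1]."""
    t0, t1, t2, t3 = t_assim
    if tmean <= t0 or tmean >= t3:
        return 0.0
    if tmean < t1:
        return (tmean - t0) / (t1 - t0)
    if tmean <= t2:
        return 1.0
    return (t3 - tmean) / (t3 - t2)


# ---------------------------------------------------------------------------
# Water and N stress
# ---------------------------------------------------------------------------
def root_fractions(state: CropState, variant: GrowthVariant, z_top: np.ndarray,
                   z_bot: np.ndarray) -> np.ndarray:
    """Root distribution over soil cells, summing to 1 within the rooted zone."""
    depth = max(state.root_depth, 1e-6)
    frac = np.zeros(len(z_top))
    for i in range(len(z_top)):
        top, bot = z_top[i], min(z_bot[i], depth)
        if top >= depth:
            break
        span = bot - top
        if variant.root_distribution == "uniform":
            w = span
        elif variant.root_distribution == "exponential":
            scale = max(depth / 3.0, 5.0)
            w = scale * (math.exp(-top / scale) - math.exp(-bot / scale))
        else:  # dynamic: triangular, densest at the surface, senesces at depth
            w = span * max(0.0, 1.0 - 0.5 * (top + bot) / depth)
        frac[i] = w
    s = frac.sum()
    return frac / s if s > 0 else frac


def water_n_stress(state: CropState, variant: GrowthVariant, params: GenotypeParams,
                   theta: np.ndarray, theta_fc: np.ndarray, theta_pwp: np.ndarray,
                   thickness_mm: np.ndarray, z_top: np.ndarray, z_bot: np.ndarray,
                   etc_demand: float, n_available: float, n_demand: float,
                   ) -> tuple[float, float, np.ndarray]:
    """Stress factors f_water, f_N in [0, 1] and the per-cell water supply (mm).

    Supply integrates plant-available water over the variant's root
    distribution; the gecros-like variant applies no reduction until the
    soil reaches wilting point (water is fully available above PWP).
    """
    if etc_demand < 0 or n_demand < 0:
        raise ValueError("demands must be >= 0")
    rf = root_fractions(state, variant, z_top, z_bot)
    paw = np.maximum(0.0, (theta - theta_pwp) * thickness_mm) * (rf > 0)
    if variant.id == "gecros_like":
        supply = paw.copy()  # no resistance until PWP
    else:
        rel = np.zeros_like(paw)
        span = (theta_fc - theta_pwp) * thickness_mm
        np.divide(paw, span, out=rel, where=span > 0)
        density = rf / rf.max() if rf.max() > 0 else rf  # relative root density
        supply = params.water_extraction * paw * np.minimum(1.0, rel + 0.3) * density
    f_water = 1.0 if etc_demand <= 0 else min(1.0, float(supply.sum()) / etc_demand)
    f_n = 1.0 if n_demand <= 0 else min(1.0, n_available / n_demand)
    return f_water, f_n, supply


# ---------------------------------------------------------------------------
# Daily growth
# ---------------------------------------------------------------------------
def _gross_assimilation(lai: float, srad: float, variant: GrowthVariant,
                        params: GenotypeParams) -> float:
    """Unstressed gross assimilation (kg DM/ha/d) at reference CO2."""
    if lai <= 0 or srad <= 0:
        return 0.0
    k = params.k_ext
    if variant.canopy == "big_leaf":
        fint = intercepted_fraction(lai, k, "big_leaf")
        return params.rue * fint * srad * 10.0  # g/m2 -> kg/ha
    par = 0.48 * srad
    if variant.canopy in ("multilayer3", "multilayer5"):
        n_layers = 3 if variant.canopy == "multilayer3" else 5
        d_lai = lai / n_layers
        p = 0.0
        for i in range(n_layers):
            i_abs = par * (math.exp(-k * i * d_lai) - math.exp(-k * (i + 1) * d_lai))
            i_leaf = i_abs / d_lai  # absorbed PAR per unit leaf area
            p += params.amax * (1.0 - math.exp(-params.lue * i_leaf / params.amax)) * d_lai
        return p * 10.0 * 0.7  # CH2O -> DM growth conversion
    # two-leaf: sunlit leaves near light saturation, shaded on the linear part
    f_sun, f_shade = sunlit_shaded_split(lai, k)
    i_sun = par * f_sun
    i_shade = par * f_shade
    lai_sun = (1.0 - math.exp(-k * lai)) / k
    lai_shade = max(lai - lai_sun, 1e-9)
    p_sun = params.amax * (1.0 - math.exp(-params.lue * (i_sun / max(lai_sun, 1e-9))
                                          / params.amax)) * lai_sun
    p_shade = params.amax * (1.0 - math.exp(-params.lue * (i_shade / lai_shade)
                                            / params.amax)) * lai_shade
    return (p_sun + p_shade) * 10.0 * 0.7


def _ci_factor(variant: GrowthVariant, co2: float, pathway: str,
               params: GenotypeParams) -> float:
    """Leaf-internal CO2 coupling on top of the pathway response."""
    mult = co2_response(co2, pathway, params)
    if variant.ci_scheme == "none":
        return mult
    if variant.ci_scheme == "constant_ci_ca":
        return mult  # Ci/Ca fixed: response follows ambient directly
    # coupled: Ci relaxes toward the assimilation-weighted value by a
    # two-iteration fixed point; slightly stronger response at high CO2
    ci = 0.7 * co2
    for _ in range(2):
        a_rel = co2_response(ci / 0.7, pathway, params)
        ci = 0.7 * co2 * (0.9 + 0.1 * a_rel)
    return co2_response(ci / 0.7, pathway, params)


def _partition(variant: GrowthVariant, state: CropState, params: GenotypeParams,
               f_water: float, f_n: float) -> dict[str, float]:
    """Assimilate allocation fractions per pool, summing to 1."""
    tt_rel = min(1.0, state.tt / params.tt_flowering)
    stress = min(f_water, f_n)
    if state.stage == STAGE_GRAINFILL:
        fill = min(1.0, (state.tt - params.tt_flowering)
                   / max(params.tt_maturity - params.tt_flowering, 1.0))
        grain = min(1.0, params.grain_frac_max * min(1.0, 0.4 + 1.5 * fill))
        if variant.partitioning == "optimized":
            root = min(0.05 * (1.0 + (1.0 - stress)), 1.0 - grain)
        else:
            root = min(0.05, 1.0 - grain)
        stem = max(0.0, 1.0 - grain - root)
        return {"grain": grain, "stem": stem, "root": root, "leaf": 0.0}
    # vegetative
    if variant.partitioning == "priority":
        # roots and leaves are served first, their demand tapering with age
        root = params.base_root_frac * (1.0 - 0.5 * tt_rel) * (1.5 - 0.5 * stress)
        root = min(root, 0.6)
        leaf = (1.0 - root) * (0.65 - 0.25 * tt_rel)
        stem = 1.0 - root - leaf
    elif variant.partitioning == "optimized":
        # root:shoot split shifts toward the more limiting resource
        root = params.base_root_frac * (2.0 - stress)
        root = min(root, 0.6)
        leaf = (1.0 - root) * (0.60 - 0.20 * tt_rel)
        stem = 1.0 - root - leaf
    else:  # fixed allocation pattern, stage-indexed only
        root = params.base_root_frac * (1.0 - 0.6 * tt_rel)
        leaf = (1.0 - root) * (0.62 - 0.22 * tt_rel)
        stem = 1.0 - root - leaf
    return {"grain": 0.0, "root": root, "leaf": leaf, "stem": stem}


def _senescence_rate(variant: GrowthVariant, state: CropState, params: GenotypeParams,
                     tmean: float, f_water: float, f_n: float) -> float:
    """Relative leaf senescence rate (fraction of leaf biomass per day)."""
    rate = 0.0
    drivers = variant.senescence
    tt_rel = state.tt / params.tt_maturity
    if "age" in drivers and state.tt > params.tt_flowering:
        rate += 0.012 * (state.tt - params.tt_flowering) \
            / max(params.tt_maturity - params.tt_flowering, 1.0)
    if "drought" in drivers:
        rate += 0.010 * (1.0 - f_water)
    if "nitrogen" in drivers:
        rate += 0.008 * (1.0 - f_n)
    if "self_shading" in drivers and state.lai > 4.0:
        rate += 0.008 * (state.lai - 4.0)
    if "temperature" in drivers and tmean > 28.0:
        rate += 0.004 * (tmean - 28.0)
    if "n_translocation" in drivers and state.stage == STAGE_GRAINFILL:
        # leaf N export to grain drives proportional leaf-area loss
        rate += 0.018 * tt_rel
    return min(rate, 0.2)


@dataclass
class GrowthInputs:
    srad: float  # MJ m-2 d-1
    tmean: float  # deg C
    co2: float = 360.0
    f_water: float = 1.0
    f_n: float = 1.0
    n_available: float = 1e9  # kg N/ha accessible today


def daily_growth(state: CropState, variant: GrowthVariant, env: GrowthInputs,
                 params: GenotypeParams) -> tuple[CropState, float]:
    """Advance biomass, LAI and N pools one day; return (state, N uptake demand met).

    Returns the realized N uptake (kg/ha) so the caller can debit soil
    mineral N by exactly the same amount.
    """
    if state.stage not in (STAGE_VEGETATIVE, STAGE_GRAINFILL):
        return replace(state, senesced_today=0.0, senesced_n_today=0.0), 0.0
    if env.srad < 0 or env.n_available < 0:
        raise ValueError("negative environmental supply")

    gross = _gross_assimilation(state.lai, env.srad, variant, params)
    gross *= _ci_factor(variant, env.co2, params.pathway, params)
    gross *= temperature_factor(env.tmean, params.t_assim)
    gross *= min(env.f_water, env.f_n)
    # juvenile phase: seedling reserve mobilization keeps early growth
    # near-exponential while the canopy is tiny (only when there is light)
    if env.srad > 0 and state.lai < 0.3:
        juvenile = 0.08 * state.leaf * temperature_factor(env.tmean, params.t_assim) \
            * min(env.f_water, env.f_n)
        gross = max(gross, juvenile)

    alloc = _partition(variant, state, params, env.f_water, env.f_n)
    d_leaf = gross * alloc["leaf"]
    d_stem = gross * alloc["stem"]
    d_root = gross * alloc["root"]
    d_grain = gross * alloc["grain"]

    # senescence: dead leaf tissue leaves the live pools; part of its N is
    # withdrawn before shedding and retained in the plant
    sen_rate = _senescence_rate(variant, state, params, env.tmean, env.f_water, env.f_n)
    sen_leaf = sen_rate * state.leaf
    conc_act = state.n_leaf / state.leaf if state.leaf > 0 else 0.0
    sen_n_total = sen_leaf * conc_act
    sen_n_lost = 0.4 * sen_n_total
    sen_n_retained = sen_n_total - sen_n_lost

    # leaf area dynamics per variant
    if variant.id in ("ceres_like", "sucros_like"):
        sla_eff = params.sla
    elif variant.id == "spass_like":
        sla_eff = params.sla * (1.2 - 0.5 * min(1.0, state.tt / params.tt_flowering))
    else:  # gecros: C- or N-limited expansion
        sla_eff = params.sla * min(1.0, 0.4 + 0.6 * env.f_n)
    d_lai = sla_eff * d_leaf / 10.0 - (state.lai / max(state.leaf, 1e-9)) * sen_leaf
    lai = max(0.0, state.lai + d_lai)

    leaf = state.leaf + d_leaf - sen_leaf
    stem = state.stem + d_stem
    root = state.root + d_root
    grain = state.grain + d_grain

    # --- nitrogen -----------------------------------------------------------
    n_leaf = state.n_leaf - sen_n_total
    n_stem = state.n_stem
    n_root = state.n_root
    n_grain = state.n_grain
    if state.stage == STAGE_GRAINFILL:
        n_grain += sen_n_retained
    else:
        n_stem += sen_n_retained

    demand_leaf = max(0.0, leaf * params.leaf_n_conc - n_leaf)
    demand_stem = max(0.0, stem * params.stem_n_conc - n_stem)
    demand_root = max(0.0, root * params.root_n_conc - n_root)
    demand_grain = max(0.0, grain * params.grain_n_conc - n_grain)
    demand = demand_leaf + demand_stem + demand_root + demand_grain

    uptake = min(demand, env.n_available)
    if demand > 0 and uptake > 0:
        scale = uptake / demand
        n_leaf += scale * demand_leaf
        n_stem += scale * demand_stem
        n_root += scale * demand_root
        n_grain += scale * demand_grain

    if state.stage == STAGE_GRAINFILL:
        # unmet grain N demand is met by translocation from leaf then stem
        unmet = max(0.0, grain * params.grain_n_conc - n_grain)
        from_leaf = min(unmet, 0.10 * n_leaf)
        n_leaf -= from_leaf
        n_grain += from_leaf
        unmet -= from_leaf
        from_stem = min(unmet, 0.10 * n_stem)
        n_stem -= from_stem
        n_grain += from_stem

    root_depth = min(params.max_root_depth,
                     state.root_depth + params.root_growth_rate)

    new = replace(
        state, lai=lai, leaf=leaf, stem=stem, root=root, grain=grain,
        n_leaf=n_leaf, n_stem=n_stem, n_root=n_root, n_grain=n_grain,
        root_depth=root_depth,
        cum_assimilation=state.cum_assimilation + gross,
        cum_senesced=state.cum_senesced + sen_leaf,
        cum_n_uptake=state.cum_n_uptake + uptake,
        cum_n_senesced=state.cum_n_senesced + sen_n_lost,
        senesced_today=sen_leaf, senesced_n_today=sen_n_lost,
    )
    return new, uptake


def finalize_season(state: CropState, params: GenotypeParams) -> dict:
    """Season outputs: yield (t/ha dry matter), grain N (%), phenology dates."""
    if state.planting_doy is None:
        raise ValueError("crop was never sown")
    yield_t = state.grain / 1000.0
    grain_n_pct = 100.0 * state.n_grain / state.grain if state.grain > 0 else 0.0
    return {
        "grain_yield": yield_t,
        "grain_n_pct": grain_n_pct,
        "planting_doy": state.planting_doy,
        "flowering_doy": state.flowering_doy,
        "maturity_doy": state.maturity_doy,
    }
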