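"""Monthly carbon and water dynamics for one grid of cells.

A CENTURY-style carbon-only scheme: maximum monthly production rates are
scaled by multiplicative temperature, water, CO2 and light/shading scalars;
NPP is allocated to live pools with fixed fractions; turnover feeds dead
pools by timelag class; dead and soil pools decay first-order down a chain
(litter -> active -> slow -> passive) with temperature and moisture
modifiers; and a two-bucket soil water model closes the water balance.
Nitrogen is not cycled -- nutrient limitation is folded into the calibrated
maximum production rates.

All functions operate elementwise on scalars or same-shaped arrays of cells.
"""

from __future__ import annotations

import numpy as np

from .climate import MONTH_LENGTHS
from .params import (AllocationParams, AllometryParams, DecompositionParams,
                     ProductionParams, SoilParams)

__all__ = [
    "LIVE_TREE_POOLS",
    "LIVE_GRASS_POOLS",
    "DEAD_POOLS",
    "SOIL_POOLS",
    "ALL_POOLS",
    "aboveground_tree_c",
    "penman_pet",
    "water_scalar",
    "temperature_scalar",
    "co2_scalars",
    "tree_production",
    "grass_production",
    "allocate_and_turnover",
    "decompose",
    "soil_water_update",
    "graze",
    "allometry",
]

LIVE_TREE_POOLS = ("tree_leaf", "tree_fine_branch", "tree_large_wood",
                   "tree_fine_root", "tree_coarse_root")
LIVE_GRASS_POOLS = ("grass_shoot", "grass_root")
DEAD_POOLS = ("grass_standing_dead", "litter_1h", "litter_10h",
              "litter_100h", "litter_1000h")
SOIL_POOLS = ("soil_active", "soil_slow", "soil_passive")
ALL_POOLS = LIVE_TREE_POOLS + LIVE_GRASS_POOLS + DEAD_POOLS + SOIL_POOLS

GRAZING_MONTHS = frozenset(range(4, 10))  # April..September
GRAZING_FRACTION = 0.30


def aboveground_tree_c(pools: dict):
    """Live aboveground tree carbon: leaf + fine branch + large wood."""
    return pools["tree_leaf"] + pools["tree_fine_branch"] + pools["tree_large_wood"]


# ---------------------------------------------------------------------------
# PET (Penman combination equation, monthly)
# ---------------------------------------------------------------------------

_SOLAR_CONSTANT = 0.0820  # MJ m^-2 min^-1
_PSYCHROMETRIC = 0.066    # kPa / degC
_LATENT_HEAT = 2.45       # MJ kg^-1
_MID_MONTH_DOY = np.array([15, 46, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349])


def _extraterrestrial_radiation(month: int, lat_deg: float) -> float:
    """Daily extraterrestrial radiation Ra (MJ m^-2 d^-1) at mid-month."""
    doy = _MID_MONTH_DOY[month - 1]
    phi = np.deg2rad(lat_deg)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * doy / 365.0)
    delta = 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)
    ws = np.arccos(np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0))
    return (24.0 * 60.0 / np.pi) * _SOLAR_CONSTANT * dr * (
        ws * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(ws))


def penman_pet(tmean, vpd_pa, wind_m_s, month: int, tmax=None, tmin=None,
               lat_deg: float = 43.5, rn=None):
    """Monthly potential evapotranspiration (cm month^-1), Penman combination.

    ``PET = [Delta/(Delta+gamma)] Rn/lambda + [gamma/(Delta+gamma)] f(u) D / lambda``

    with the slope of the saturation curve ``Delta``, a Hargreaves-type net
    radiation estimate from the diurnal temperature range (unless ``rn``,
    MJ m^-2 d^-1, is supplied), and the classical linear wind function
    ``f(u) = 6.43 (1 + 0.536 u)`` acting on the vapor pressure deficit ``D``
    in kPa.  Nonnegative; increases with temperature and with VPD.
    """
    t = np.asarray(tmean, float)
    d_kpa = np.maximum(np.asarray(vpd_pa, float), 0.0) / 1000.0
    u = np.maximum(np.asarray(wind_m_s, float), 0.0)

    es = 0.6108 * np.exp(17.27 * t / (t + 237.3))
    slope = 4098.0 * es / (t + 237.3) ** 2

    if rn is None:
        ra = _extraterrestrial_radiation(month, lat_deg)
        trange = (np.maximum(np.asarray(tmax, float) - np.asarray(tmin, float), 0.0)
                  if tmax is not None else np.full_like(t, 12.0))
        rs = 0.16 * np.sqrt(trange) * ra
        rn = np.maximum(0.77 * rs - 1.5, 0.0)  # net of a bulk longwave loss

    e_rad = slope / (slope + _PSYCHROMETRIC) * np.asarray(rn, float) / _LATENT_HEAT
    e_aero = (_PSYCHROMETRIC / (slope + _PSYCHROMETRIC)
              * 6.43 * (1.0 + 0.536 * u) * d_kpa / _LATENT_HEAT)
    pet_mm_day = np.maximum(e_rad, 0.0) + np.maximum(e_aero, 0.0)
    # no evaporative demand from frozen surfaces
    pet_mm_day = np.where(t < 0.0, 0.0, pet_mm_day)
    return pet_mm_day * MONTH_LENGTHS[month - 1] / 10.0


# ---------------------------------------------------------------------------
# production scalars
# ---------------------------------------------------------------------------

def water_scalar(available_cm, pet_cm, params: ProductionParams, tree: bool):
    """Production water scalar from the available-water-to-PET ratio.

    A saturating ramp reaching 1 at ``water_sat_ratio``; the tree curve
    (exponent < 1) is the less steep, drought-tolerant one.
    """
    pet = np.maximum(np.asarray(pet_cm, float), 1e-6)
    ratio = np.maximum(np.asarray(available_cm, float), 0.0) / pet
    x = np.clip(ratio / params.water_sat_ratio, 0.0, 1.0)
    exp = params.tree_water_exp if tree else params.grass_water_exp
    return np.maximum(x ** exp, params.water_floor)


def temperature_scalar(tmean, params: ProductionParams, tree: bool):
    """Gaussian temperature response with a hard frost cutoff."""
    t = np.asarray(tmean, float)
    opt = params.tree_t_opt if tree else params.grass_t_opt
    width = params.tree_t_width if tree else params.grass_t_width
    s = np.exp(-((t - opt) / width) ** 2)
    return np.where(t <= params.frost_cutoff, 0.0, s)


def co2_scalars(co2_ppm, params: ProductionParams, effects_on: bool = True):
    """(production multiplier, transpiration multiplier) at a CO2 level.

    Logarithmic in concentration: at double the reference, production is
    multiplied by ``1 + co2_prod_beta`` (default +15%) and transpiration by
    ``1 - co2_transp_beta`` (default -25%, floored at a positive minimum).
    With effects off both multipliers are 1.
    """
    c = np.asarray(co2_ppm, float)
    if np.any(c <= 0) or params.co2_ref <= 0:
        raise ValueError("CO2 concentrations must be positive")
    if not effects_on:
        one = np.ones_like(c)
        return one, one
    log2r = np.log2(c / params.co2_ref)
    prod = 1.0 + params.co2_prod_beta * log2r
    transp = np.maximum(1.0 - params.co2_transp_beta * log2r,
                        params.co2_transp_floor)
    return prod, transp


def tree_production(params: ProductionParams, t_scalar, w_scalar, co2_prod,
                    lai, grass_root=0.0):
    """Tree NPP (g C m^-2 month^-1): max rate times the scalar product.

    The light scalar is a Beer-law saturating function of the tree's own
    LAI raised to a power >= 1 (sparse canopies capture disproportionately
    little light), with an optional establishment floor.  Grass competes
    against tree regeneration: production is further damped by grass root
    carbon in proportion to the open-canopy fraction, so closed canopies
    are unaffected while seedlings facing an established grass sod are
    suppressed.  Roots survive fire, so a burn does not open a
    competition-free window for tree establishment.
    """
    canopy = 1.0 - np.exp(-params.light_k * np.asarray(lai, float))
    light = np.maximum(canopy ** params.light_power, params.light_floor)
    comp = np.exp(-params.grass_competition_k
                  * np.asarray(grass_root, float) * (1.0 - canopy))
    return params.max_tree_npp * t_scalar * w_scalar * co2_prod * light * comp


def grass_production(params: ProductionParams, t_scalar, w_scalar, co2_prod,
                     tree_lai, standing_dead):
    """Grass NPP with shading by tree canopy and standing dead grass."""
    shade = np.exp(-params.shade_k_lai * np.asarray(tree_lai, float)
                   - params.shade_k_dead * np.asarray(standing_dead, float))
    return params.max_grass_npp * t_scalar * w_scalar * co2_prod * shade


# ---------------------------------------------------------------------------
# allocation, turnover, decomposition
# ---------------------------------------------------------------------------

def allocate_and_turnover(pools: dict, tree_npp, grass_npp,
                          params: AllocationParams) -> None:
    """Distribute NPP to live pools and apply turnover to dead pools.

    Turnover routes live carbon to the dead pool of matching timelag class:
    leaf and fine material to 1-h/10-h litter, fine branch to 100-h, large
    wood to 1000-h, roots to the active soil pool; grass shoots pass through
    standing dead before falling to 1-h litter.  Total carbon is conserved.
    Modifies ``pools`` in place.
    """
    if abs(sum(params.tree_alloc.values()) - 1.0) > 1e-9:
        raise ValueError("tree allocation fractions must sum to 1")
    if abs(sum(params.grass_alloc.values()) - 1.0) > 1e-9:
        raise ValueError("grass allocation fractions must sum to 1")

    for pool, frac in params.tree_alloc.items():
        pools[f"tree_{pool}"] = pools[f"tree_{pool}"] + frac * tree_npp
    for pool, frac in params.grass_alloc.items():
        pools[f"grass_{pool}"] = pools[f"grass_{pool}"] + frac * grass_npp

    leaf_out = pools["tree_leaf"] * params.tree_turnover["leaf"]
    pools["tree_leaf"] = pools["tree_leaf"] - leaf_out
    pools["litter_1h"] = pools["litter_1h"] + params.leaf_to_1h * leaf_out
    pools["litter_10h"] = pools["litter_10h"] + (1.0 - params.leaf_to_1h) * leaf_out

    for pool, dest in (("fine_branch", "litter_100h"),
                       ("large_wood", "litter_1000h"),
                       ("fine_root", "soil_active"),
                       ("coarse_root", "soil_active")):
        out = pools[f"tree_{pool}"] * params.tree_turnover[pool]
        pools[f"tree_{pool}"] = pools[f"tree_{pool}"] - out
        pools[dest] = pools[dest] + out

    shoot_out = pools["grass_shoot"] * params.grass_turnover["shoot"]
    pools["grass_shoot"] = pools["grass_shoot"] - shoot_out
    pools["grass_standing_dead"] = pools["grass_standing_dead"] + shoot_out
    fall = pools["grass_standing_dead"] * params.standing_dead_fall
    pools["grass_standing_dead"] = pools["grass_standing_dead"] - fall
    pools["litter_1h"] = pools["litter_1h"] + fall

    root_out = pools["grass_root"] * params.grass_turnover["root"]
    pools["grass_root"] = pools["grass_root"] - root_out
    pools["soil_active"] = pools["soil_active"] + root_out


_DECAY_CHAIN = {
    "grass_standing_dead": None,  # handled in turnover (falls, does not decay)
    "litter_1h": "soil_active",
    "litter_10h": "soil_active",
    "litter_100h": "soil_active",
    "litter_1000h": "soil_active",
    "soil_active": "soil_slow",
    "soil_slow": "soil_passive",
    "soil_passive": None,
}


def decompose(pools: dict, tmean, moisture_ratio, params: DecompositionParams):
    """One month of first-order decay; returns heterotrophic respiration.

    Per-pool base rates are scaled by a Q10 temperature factor (zero below
    freezing) and a saturating moisture factor of the available-water-to-PET
    ratio (the same wetness driver production responds to).  The
    respired fraction leaves the system; the remainder moves down the chain
    (litter -> active -> slow -> passive; passive decay is fully respired).
    Modifies ``pools`` in place.
    """
    t = np.asarray(tmean, float)
    f_t = np.where(t <= 0.0, 0.0, params.q10 ** ((t - params.t_ref) / 10.0))
    f_t = np.minimum(f_t, 2.5)
    f_m = np.clip(np.asarray(moisture_ratio, float) / params.moisture_half,
                  0.0, 1.0)
    mod = f_t * f_m

    rh = 0.0
    for pool, rate in params.base_rates.items():
        dest = _DECAY_CHAIN[pool]
        decayed = pools[pool] * np.minimum(rate * mod, 1.0)
        pools[pool] = pools[pool] - decayed
        if dest is None:
            rh = rh + decayed
        else:
            resp = params.respired_overrides.get(
                pool, params.respired_fraction) * decayed
            pools[dest] = pools[dest] + (decayed - resp)
            rh = rh + resp
    return rh


# ---------------------------------------------------------------------------
# soil water and grazing
# ---------------------------------------------------------------------------

def soil_water_update(sw1, sw2, cap1, cap2, precip_cm, pet_cm,
                      transp_mult=1.0, demand_factor: float = 0.8):
    """One month of the two-bucket water balance.

    Precipitation fills the top layer then the bottom; excess beyond total
    capacity drains.  AET is the lesser of the evaporative demand
    (``PET * demand_factor * transp_mult``) and the water available, drawn
    from the layers in proportion to their contents.  Returns
    ``(sw1, sw2, aet, drainage)`` with ``aet <= pet`` guaranteed.
    """
    sw1 = np.asarray(sw1, float).copy()
    sw2 = np.asarray(sw2, float).copy()
    p = np.maximum(np.asarray(precip_cm, float), 0.0)
    pet = np.maximum(np.asarray(pet_cm, float), 0.0)

    room1 = np.maximum(cap1 - sw1, 0.0)
    to1 = np.minimum(p, room1)
    sw1 = sw1 + to1
    rest = p - to1
    room2 = np.maximum(cap2 - sw2, 0.0)
    to2 = np.minimum(rest, room2)
    sw2 = sw2 + to2
    drainage = rest - to2

    demand = pet * demand_factor * np.asarray(transp_mult, float)
    available = sw1 + sw2
    aet = np.minimum(np.minimum(demand, available), pet)
    with np.errstate(invalid="ignore", divide="ignore"):
        share1 = np.where(available > 0, sw1 / np.where(available > 0, available, 1.0), 0.0)
    sw1 = sw1 - aet * share1
    sw2 = sw2 - aet * (1.0 - share1)
    return sw1, sw2, aet, drainage


def graze(shoot_npp, month: int, enabled: bool = True):
    """Grazed carbon: 30% of monthly aboveground grass NPP, April-September."""
    npp = np.maximum(np.asarray(shoot_npp, float), 0.0)
    if not enabled or month not in GRAZING_MONTHS:
        return np.zeros_like(npp)
    return GRAZING_FRACTION * npp


# ---------------------------------------------------------------------------
# tree allometry
# ---------------------------------------------------------------------------

def allometry(pools: dict, params: AllometryParams) -> dict:
    """Average-tree geometry from tree carbon pools.

    Height is a power law of aboveground tree C; crown base height is height
    times one minus a crown ratio that shrinks as stands grow tall (a stand
    age proxy); bark thickness is proportional to height; LAI saturates in
    leaf C at the (halved) asymptote.  Zero pools give zero geometry.
    """
    ag = np.maximum(aboveground_tree_c(pools), 0.0)
    height = params.height_a * ag ** params.height_b
    age_frac = np.clip(height / params.crown_ratio_height_scale, 0.0, 1.0)
    crown_ratio = (params.crown_ratio_young
                   + (params.crown_ratio_old - params.crown_ratio_young) * age_frac)
    cbh = height * (1.0 - crown_ratio)
    bark = params.bark_c * height
    lai = params.lai_max * (1.0 - np.exp(-params.lai_k
                                         * np.maximum(pools["tree_leaf"], 0.0)))
    return {"height": height, "cbh": cbh, "bark_cm": bark, "lai": lai}
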