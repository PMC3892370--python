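"""Fire danger, behavior, effects and management policies.

Surface fire behavior follows the Rothermel spread model over a fuel bed
assembled from the cell's carbon pools (1-h/10-h/100-h dead classes plus
live fine fuel), with moisture damping against class-specific moistures of
extinction and a vegetation-class wind speed (grassland windier than
forest).  Fireline intensity is Byram's H*w*R; the energy release component
is the flaming-front energy release of the consumed fuel per unit area.
Crown-fire initiation uses the critical-intensity criterion from crown base
height and foliar moisture; crown fires kill all live tree carbon, while
surface-fire stem mortality rises with crown scorch and falls with bark
thickness.  All functions are deterministic and vectorized over cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import FireParams

__all__ = [
    "fuel_loads",
    "fire_behavior",
    "ignition_test",
    "crown_fire_test",
    "burn_fraction",
    "fire_effects",
    "suppression_policy",
    "prescribed_event_years",
    "FireEvent",
]

# unit conversions for the Rothermel core (internally in US customary units)
_KG_M2_TO_LB_FT2 = 0.204816
_PER_M_TO_PER_FT = 0.3048
_FT_MIN_TO_M_S = 0.00508
_M_S_TO_FT_MIN = 196.85
_KG_M3_TO_LB_FT3 = 0.0624280
_BTU_LB = 8000.0  # low heat of combustion used inside the spread core


@dataclass
class FireEvent:
    """One simulated fire on one cell."""

    year: int
    doy: int
    cell: int
    ros: float          # m s^-1
    fli: float          # kW m^-1
    erc: float          # kW m^-2
    crown: bool
    burn_fraction: float
    suppressed: bool = False
    prescribed: bool = False


def fuel_loads(pools: dict, params: FireParams | None = None) -> dict:
    """Per-class fuel loads (g dry matter m^-2) from carbon pools.

    Dead classes map from the matching dead pools (standing dead grass
    counts as 1-h fuel); live fine fuel is grass shoot plus tree leaf.
    """
    params = params or FireParams()
    f = params.c_to_dry_matter
    return {
        "1h": (pools["litter_1h"] + pools["grass_standing_dead"]) * f,
        "10h": pools["litter_10h"] * f,
        "100h": pools["litter_100h"] * f,
        "1000h": pools["litter_1000h"] * f,
        "live": (pools["grass_shoot"] + pools["tree_leaf"]) * f,
    }


def fire_behavior(fuels: dict, moistures: dict, grass_dominated,
                  params: FireParams | None = None,
                  wind_m_s=None):
    """Rothermel surface spread rate, fireline intensity and energy release.

    ``fuels`` holds g DM m^-2 loads per class, ``moistures`` dead-fuel
    moisture fractions per timelag class (1h/10h/100h) -- typically from
    :func:`vegfire.fwi.fuel_moistures`.  ``grass_dominated`` selects the
    grassland fuel-bed properties and wind speed per cell.  Returns
    ``(ros m s^-1, fli kW m^-1, erc kW m^-2)``.  ROS is zero wherever the
    fine dead fuel moisture is at or above the moisture of extinction.
    """
    params = params or FireParams()
    grass = np.asarray(grass_dominated, bool)

    w1 = np.asarray(fuels["1h"], float) / 1000.0   # kg m^-2
    w10 = np.asarray(fuels["10h"], float) / 1000.0
    w100 = np.asarray(fuels["100h"], float) / 1000.0
    wlive = np.asarray(fuels["live"], float) / 1000.0

    sav1 = np.where(grass, params.sav["1h_grass"], params.sav["1h_forest"])
    s1 = sav1 * _PER_M_TO_PER_FT          # 1/ft
    s10 = params.sav["10h"] * _PER_M_TO_PER_FT
    s100 = params.sav["100h"] * _PER_M_TO_PER_FT
    slive = params.sav["live"] * _PER_M_TO_PER_FT

    l1 = w1 * _KG_M2_TO_LB_FT2            # lb ft^-2
    l10 = w10 * _KG_M2_TO_LB_FT2
    l100 = w100 * _KG_M2_TO_LB_FT2
    llive = wlive * _KG_M2_TO_LB_FT2

    m1 = np.asarray(moistures["1h"], float)
    m10 = np.asarray(moistures["10h"], float)
    m100 = np.asarray(moistures["100h"], float)
    mx_dead = np.where(grass, params.mx_dead_grass, params.mx_dead_forest)

    dead_sw = s1 * l1 + s10 * l10 + s100 * l100
    total_sw = dead_sw + slive * llive
    total_load = l1 + l10 + l100 + llive
    ok = (total_sw > 0) & (total_load > 0)
    dead_sw_safe = np.where(dead_sw > 0, dead_sw, 1.0)
    total_sw_safe = np.where(ok, total_sw, 1.0)

    # load-weighted dead fuel moisture (sav-weighted, Rothermel style)
    mf_dead = (s1 * l1 * m1 + s10 * l10 * m10 + s100 * l100 * m100) / dead_sw_safe
    sigma = (s1 * (s1 * l1) + s10 * (s10 * l10) + s100 * (s100 * l100)
             + slive * (slive * llive)) / total_sw_safe
    sigma = np.maximum(sigma, 1.0)

    depth_m = np.where(grass, params.fuel_depth_grass_m, params.fuel_depth_forest_m)
    delta = depth_m / 0.3048              # ft
    rho_p = params.particle_density_kg_m3 * _KG_M3_TO_LB_FT3
    rho_b = total_load / delta
    beta = rho_b / rho_p
    beta = np.maximum(beta, 1e-6)
    beta_op = 3.348 * sigma ** (-0.8189)
    rel = beta / beta_op

    # moisture damping
    rm_dead = np.clip(mf_dead / mx_dead, 0.0, 1.0)
    eta_m_dead = np.clip(1.0 - 2.59 * rm_dead + 5.11 * rm_dead ** 2
                         - 3.52 * rm_dead ** 3, 0.0, 1.0)
    eta_m_dead = np.where(mf_dead >= mx_dead, 0.0, eta_m_dead)
    rm_live = np.clip(params.live_fuel_moisture / params.mx_live, 0.0, 1.0)
    eta_m_live = np.clip(1.0 - 2.59 * rm_live + 5.11 * rm_live ** 2
                         - 3.52 * rm_live ** 3, 0.0, 1.0)
    eta_s = 0.174 * params.effective_mineral ** (-0.19)

    gamma_max = sigma ** 1.5 / (495.0 + 0.0594 * sigma ** 1.5)
    a_exp = 133.0 * sigma ** (-0.7913)
    gamma = gamma_max * rel ** a_exp * np.exp(a_exp * (1.0 - rel))

    net_dead = (l1 + l10 + l100) * (1.0 - params.mineral_content)
    net_live = llive * (1.0 - params.mineral_content)
    ir = gamma * _BTU_LB * eta_s * (net_dead * eta_m_dead + net_live * eta_m_live)

    xi = np.exp((0.792 + 0.681 * np.sqrt(sigma)) * (beta + 0.1)) \
        / (192.0 + 0.2595 * sigma)

    if wind_m_s is None:
        wind_m_s = np.where(grass, params.wind_grass, params.wind_forest)
    u_ftmin = np.asarray(wind_m_s, float) * _M_S_TO_FT_MIN
    c = 7.47 * np.exp(-0.133 * sigma ** 0.55)
    b = 0.02526 * sigma ** 0.54
    e = 0.715 * np.exp(-3.59e-4 * sigma)
    phi_w = c * u_ftmin ** b * rel ** (-e)

    eps = np.exp(-138.0 / sigma)
    q_ig = 250.0 + 1116.0 * np.clip(mf_dead, 0.0, 3.0)

    denom = rho_b * eps * q_ig
    ros_ftmin = np.where(ok & (denom > 0), ir * xi * (1.0 + phi_w)
                         / np.where(denom > 0, denom, 1.0), 0.0)
    ros = np.maximum(ros_ftmin, 0.0) * _FT_MIN_TO_M_S
    # damping cutoff: no spread at/above the moisture of extinction
    ros = np.where(mf_dead >= mx_dead, 0.0, ros)

    # consumed fuel in the flaming front, kg m^-2
    cons = params.consumption
    w_flame = (cons["litter_1h"] * w1 + cons["litter_10h"] * w10
               + cons["litter_100h"] * w100
               + params.grass_shoot_consumption * wlive)
    fli = params.heat_yield_kj_kg * w_flame * ros          # kW m^-1
    erc = params.heat_yield_kj_kg * w_flame / params.residence_time_s  # kW m^-2
    erc = np.where(ros > 0, erc, 0.0)
    return ros, fli, erc


def ignition_test(ros, ffmc, bui_value, fire_done_this_year,
                  params: FireParams | None = None):
    """Deterministic natural-ignition gate.

    True iff the spread rate is positive, FFMC exceeds its threshold, BUI
    exceeds its threshold, and no fire has yet occurred this calendar year
    (at most one fire per cell-year, on the first qualifying day).
    """
    params = params or FireParams()
    return (np.asarray(ros, float) > 0.0) \
        & (np.asarray(ffmc, float) > params.ffmc_threshold) \
        & (np.asarray(bui_value, float) > params.bui_threshold) \
        & ~np.asarray(fire_done_this_year, bool)


def crown_fire_test(fli, crown_base_height, foliar_moisture_pct: float = 100.0):
    """Crown-fire initiation: FLI at or above the critical intensity.

    ``I0 = (0.01 * CBH * (460 + 25.9 * FMC)) ** 1.5`` kW m^-1 with CBH in m
    and foliar moisture in percent.  CBH -> 0 gives crowning at any
    positive intensity.
    """
    cbh = np.maximum(np.asarray(crown_base_height, float), 0.0)
    i0 = (0.01 * cbh * (460.0 + 25.9 * foliar_moisture_pct)) ** 1.5
    return np.asarray(fli, float) >= i0


def burn_fraction(years_since_fire, ramp_years: float = 10.0):
    """Fraction of the cell burned: min(years_since_fire / ramp, 1).

    Fine fuels take about a decade to rebuild after a burn, so fires within
    ``ramp_years`` of the previous one burn only part of the cell (0.1 one
    year after a fire).  A cell cannot reburn within its fire year, so
    ``years_since_fire`` must be >= 1.
    """
    y = np.asarray(years_since_fire, float)
    if np.any(y < 1):
        raise ValueError("years since fire must be >= 1")
    return np.minimum(y / ramp_years, 1.0)


def _surface_mortality(fli, cbh, bark_cm, params: FireParams):
    """Stem-kill fraction for a surface fire."""
    scorch = params.scorch_coef * np.maximum(np.asarray(fli, float), 0.0) \
        ** params.scorch_exp
    z = (scorch - np.asarray(cbh, float)) / params.mortality_logistic_scale
    crown_kill = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
    bark_survival = np.exp(-np.asarray(bark_cm, float) / params.bark_survival_scale_cm)
    return crown_kill * bark_survival


def fire_effects(pools: dict, fli, crown, burn_frac,
                 cbh=0.0, bark_cm=0.0, params: FireParams | None = None,
                 tree_mortality_override=None, grass_consumption=None) -> dict:
    """Apply one fire to the carbon pools (in place).

    Crown fires kill all live tree carbon; surface fires kill the fraction
    given by scorch vs. crown base height times a bark-thickness survival
    factor.  Killed live carbon transfers to the dead pool of matching
    timelag class except for an emitted fraction of fine material; dead-fuel
    consumption leaves as emission; grass shoots and standing dead are
    mostly consumed, roots survive.  All changes scale with ``burn_frac``.

    Returns a dict with ``emissions`` and ``killed_live`` (g C m^-2).
    """
    params = params or FireParams()
    bf = np.asarray(burn_frac, float)
    crown = np.asarray(crown, bool)

    if tree_mortality_override is not None:
        mort = np.asarray(tree_mortality_override, float)
    else:
        mort = np.where(crown, 1.0, _surface_mortality(fli, cbh, bark_cm, params))
    kill = np.clip(mort, 0.0, 1.0) * bf

    shape = np.broadcast_shapes(bf.shape, np.shape(pools["tree_leaf"]))
    emissions = np.zeros(shape)
    killed_total = np.zeros(shape)

    # live tree pools
    fe = params.killed_fine_emission
    for pool, dest, fine in (
        ("tree_leaf", "litter_1h", True),
        ("tree_fine_branch", "litter_100h", True),
        ("tree_large_wood", "litter_1000h", False),
        ("tree_fine_root", "soil_active", False),
        ("tree_coarse_root", "soil_active", False),
    ):
        killed = pools[pool] * kill
        pools[pool] = pools[pool] - killed
        emitted = killed * (fe if fine else 0.0)
        pools[dest] = pools[dest] + (killed - emitted)
        emissions += emitted
        killed_total += killed

    # dead fuel consumption
    for pool, frac in params.consumption.items():
        burned = pools[pool] * frac * bf
        pools[pool] = pools[pool] - burned
        emissions += burned

    # grass: shoots and standing dead mostly consumed, roots survive
    gc = params.grass_shoot_consumption if grass_consumption is None \
        else grass_consumption
    for pool in ("grass_shoot", "grass_standing_dead"):
        burned = pools[pool] * gc * bf
        pools[pool] = pools[pool] - burned
        emissions += burned

    return {"emissions": emissions, "killed_live": killed_total}


def suppression_policy(ros, fli, erc, params: FireParams | None = None):
    """True where the fire is suppressed (does not escape).

    A fire escapes when its severity exceeds the scaled thresholds
    (``suppression_scale`` times the base ROS/FLI/ERC thresholds) under the
    configured rule: "any" (default; one exceedance suffices) or "all".
    """
    params = params or FireParams()
    s = params.suppression_scale
    ex_ros = np.asarray(ros, float) > s * params.ros_threshold_m_s
    ex_fli = np.asarray(fli, float) > s * params.fli_threshold_kw_m
    ex_erc = np.asarray(erc, float) > s * params.erc_threshold_kw_m2
    if params.escape_rule == "any":
        escaped = ex_ros | ex_fli | ex_erc
    else:
        escaped = ex_ros & ex_fli & ex_erc
    return ~escaped


def prescribed_event_years(year_start: int, year_end: int,
                           params: FireParams | None = None) -> np.ndarray:
    """Calendar years with a prescribed burn (start year, fixed interval)."""
    params = params or FireParams()
    years = np.arange(params.prescribed_start_year, year_end + 1,
                      params.prescribed_interval_years)
    return years[(years >= year_start) & (years <= year_end)]
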