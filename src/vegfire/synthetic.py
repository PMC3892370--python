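"""Synthetic gridded climate, soils, CO2, and future-anomaly generator.

The generator stands in for the observational archives a regional vegetation
model would normally consume.  It produces a small lattice of cells whose
mean annual temperature rises and precipitation falls along the NW -> SE
diagonal, spanning the ecotone boundary climate (7.6 degC / 48.5 cm), with

* ~48 cm yr^-1 mean precipitation, half falling May through July,
* region-wide interannual variability (lognormal precipitation multipliers,
  AR(1) temperature anomalies) shared by all cells, so droughts -- including
  scheduled severe 1930s- and 1950s-analogue episodes -- are synchronous
  across the landscape,
* vapor pressure tied to a seasonal relative-humidity target evaluated at the
  domain-mean temperature, so warm-dry cells are also the low-RH cells, and
  dry years are low-humidity years.

All randomness derives from ``SyntheticConfig.seed``; identical configs give
bit-identical outputs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import xarray as xr

from .climate import saturation_vapor_pressure
from .params import TRAJECTORY_STYLES, SyntheticConfig

__all__ = [
    "ECOTONE_TMEAN",
    "ECOTONE_PPT",
    "generate_grid",
    "generate_future_anomalies",
    "generate_co2_path",
]

#: Ecotone boundary climate: cells cooler than this (or wetter than
#: :data:`ECOTONE_PPT`) support substantial tree biomass under natural fire.
ECOTONE_TMEAN = 7.6   # deg C
ECOTONE_PPT = 48.5    # cm yr^-1

# Relative monthly precipitation weights (Jan..Dec) before rescaling the
# May-July block to the configured fraction.
_PPT_WEIGHTS = np.array([0.020, 0.025, 0.050, 0.080, 0.160, 0.190,
                         0.150, 0.080, 0.060, 0.050, 0.030, 0.025])
_MJJ = np.zeros(12, bool)
_MJJ[4:7] = True  # May, June, July

# Style-specific 2100 targets: (temperature anomaly degC, precip ratio,
# vapor-pressure sensitivity to warming).  The vapor-pressure betas are all
# below the ~0.06 K^-1 slope of the saturation curve, so relative humidity
# declines modestly under every style -- least for the wetter style, most
# for the hottest-driest one -- and vapor pressure deficit rises throughout.
_STYLE_TARGETS = {
    "wetter-warm": (2.8, 1.18, 0.045),
    "hot-flat-precip": (5.8, 1.00, 0.035),
    "hottest-driest": (6.8, 0.72, 0.025),
}
_COMMON_2040_DT = 1.2  # degC shared warming at 2040, before styles diverge


def _gradient(config: SyntheticConfig) -> np.ndarray:
    """Fractional position along the NW (0) -> SE (1) diagonal, shape (ny, nx)."""
    xs = np.linspace(0.0, 1.0, config.nx) if config.nx > 1 else np.zeros(1)
    ys = np.linspace(0.0, 1.0, config.ny) if config.ny > 1 else np.zeros(1)
    gy, gx = np.meshgrid(ys, xs, indexing="ij")
    if config.nx > 1 and config.ny > 1:
        return 0.5 * (gx + gy)
    return gx + gy


def _month_fractions(may_jul_fraction: float) -> np.ndarray:
    w = _PPT_WEIGHTS.copy()
    w[_MJJ] *= may_jul_fraction / w[_MJJ].sum()
    w[~_MJJ] *= (1.0 - may_jul_fraction) / w[~_MJJ].sum()
    return w


def _seasonal_shape() -> np.ndarray:
    """-1 in January, +1 in July."""
    m = np.arange(12)
    return -np.cos(2.0 * np.pi * m / 12.0)


def _annual_variability(config: SyntheticConfig, years: np.ndarray, rng):
    """Region-wide annual precip multipliers and temperature anomalies."""
    n = len(years)
    sig = config.precip_lognorm_sigma
    ppt_mult = np.exp(rng.normal(-0.5 * sig**2, sig, n)) if sig > 0 else np.ones(n)

    rho, sd = config.temp_ar1_rho, config.temp_ar1_sd
    t_anom = np.zeros(n)
    innov = rng.normal(0.0, sd * np.sqrt(max(1.0 - rho**2, 0.0)), n)
    for i in range(n):
        t_anom[i] = (rho * t_anom[i - 1] if i else rng.normal(0.0, sd)) + innov[i]

    for ep in config.droughts:
        in_ep = (years >= ep.start_year) & (years < ep.start_year + ep.length_years)
        ppt_mult[in_ep] *= ep.precip_multiplier
        t_anom[in_ep] += ep.temp_offset
    return ppt_mult, t_anom


def generate_grid(config: SyntheticConfig | None = None):
    """Generate the historical climate grid and soil grid.

    Returns ``(climate, soils)`` where ``climate`` is the monthly
    ``(time, y, x)`` dataset described in :mod:`vegfire.climate` and
    ``soils`` is a ``(y, x)`` dataset with ``depth_cm``, ``awc_per_cm``
    and ``bulk_density``.
    """
    config = config or SyntheticConfig()
    t_lo, t_hi = sorted((config.tmean_nw, config.tmean_se))
    p_lo, p_hi = sorted((config.ppt_nw, config.ppt_se))
    if not (t_lo < ECOTONE_TMEAN < t_hi) or not (p_lo < ECOTONE_PPT < p_hi):
        warnings.warn(
            "gradient endpoints do not bracket the ecotone boundary "
            f"({ECOTONE_TMEAN} degC / {ECOTONE_PPT} cm)", stacklevel=2)

    rng = np.random.default_rng((config.seed, 101))
    years = np.arange(config.year_start, config.year_end + 1)
    nyr, ny, nx = len(years), config.ny, config.nx

    d = _gradient(config)
    tmean_cell = config.tmean_nw + d * (config.tmean_se - config.tmean_nw)
    ppt_cell = config.ppt_nw + d * (config.ppt_se - config.ppt_nw)

    season = _seasonal_shape()
    mfrac = _month_fractions(config.may_jul_fraction)
    dr = (config.diurnal_range_winter
          + (config.diurnal_range_summer - config.diurnal_range_winter)
          * 0.5 * (season + 1.0))
    rh_target = (config.rh_winter
                 + (config.rh_summer - config.rh_winter) * 0.5 * (season + 1.0))

    ppt_mult, t_anom = _annual_variability(config, years, rng)
    sig_m = config.precip_month_sigma
    month_noise = (np.exp(rng.normal(-0.5 * sig_m**2, sig_m, (nyr, 12)))
                   if sig_m > 0 else np.ones((nyr, 12)))

    # monthly mean temperature per (year, month, y, x)
    tmean = (tmean_cell[None, None]
             + config.seasonal_t_amplitude * season[None, :, None, None]
             + t_anom[:, None, None, None])
    tmax = tmean + 0.5 * dr[None, :, None, None]
    tmin = tmean - 0.5 * dr[None, :, None, None]

    ppt = (ppt_cell[None, None] * mfrac[None, :, None, None]
           * ppt_mult[:, None, None, None] * month_noise[:, :, None, None])

    # vapor pressure: uniform over the grid, from RH target at domain-mean T
    t_ref = (0.5 * (config.tmean_nw + config.tmean_se)
             + config.seasonal_t_amplitude * season[None, :]
             + t_anom[:, None])
    humid_mult = ppt_mult ** config.vpr_precip_exp
    vpr_flat = (rh_target[None, :] * saturation_vapor_pressure(t_ref)
                * humid_mult[:, None])
    vpr = np.broadcast_to(vpr_flat[:, :, None, None], tmean.shape).copy()
    vpr = np.minimum(vpr, saturation_vapor_pressure(tmean))

    shape = (nyr * 12, ny, nx)
    time = np.arange(nyr * 12)
    year_c = np.repeat(years, 12)
    month_c = np.tile(np.arange(1, 13), nyr)
    climate = xr.Dataset(
        {
            "ppt": (("time", "y", "x"), ppt.reshape(shape)),
            "tmax": (("time", "y", "x"), tmax.reshape(shape)),
            "tmin": (("time", "y", "x"), tmin.reshape(shape)),
            "vpr": (("time", "y", "x"), vpr.reshape(shape)),
        },
        coords={"time": time, "year": ("time", year_c), "month": ("time", month_c),
                "y": np.arange(ny), "x": np.arange(nx)},
        attrs={"seed": config.seed},
    )
    soils = xr.Dataset(
        {
            "depth_cm": (("y", "x"), np.full((ny, nx), config.soil_depth_cm)),
            "awc_per_cm": (("y", "x"), np.full((ny, nx), config.soil_awc_per_cm)),
            "bulk_density": (("y", "x"), np.full((ny, nx), config.soil_bulk_density)),
        },
        coords={"y": np.arange(ny), "x": np.arange(nx)},
    )
    return climate, soils


def generate_future_anomalies(style: str,
                              config: SyntheticConfig | None = None) -> xr.Dataset:
    """Monthly 2001-2100 anomalies on a 2x2 coarse lattice for one style.

    Styles: ``wetter-warm`` (modest warming, wetter), ``hot-flat-precip``
    (>5 degC decadal-mean warming by 2100, unchanged precipitation), and
    ``hottest-driest`` (largest warming, reduced precipitation).  All styles
    share a common warming ramp to 2040 and diverge afterwards.
    """
    if style not in TRAJECTORY_STYLES:
        raise ValueError(f"unknown trajectory style {style!r}; "
                         f"expected one of {TRAJECTORY_STYLES}")
    config = config or SyntheticConfig()
    dt_2100, pratio_2100, vpr_beta = _STYLE_TARGETS[style]

    rng = np.random.default_rng(
        (config.seed, 211, TRAJECTORY_STYLES.index(style)))
    years = np.arange(config.future_year_start, config.future_year_end + 1)
    nyr = len(years)
    y0 = config.future_year_start - 1

    frac40 = np.clip((years - y0) / (2040 - y0), 0.0, 1.0)
    frac2100 = np.clip((years - 2040) / (config.future_year_end - 2040), 0.0, 1.0)
    dt_trend = _COMMON_2040_DT * frac40 + (dt_2100 - _COMMON_2040_DT) * frac2100
    pr_trend = 1.0 + (pratio_2100 - 1.0) * frac2100

    # GCM-like interannual variability on top of the smooth trends, with the
    # same statistical structure as the historical generator (zero-mean, so
    # multi-year means stay smooth): lognormal annual precipitation
    # multipliers, AR(1) temperature anomalies, and humidity tracking dry
    # years.
    # Interannual variability with the same statistical structure as the
    # historical generator (persistent AR(1) temperature anomalies,
    # lognormal precipitation multipliers), so droughts at least as deep as
    # the historical record arise in every trajectory.
    sig = config.precip_lognorm_sigma
    pmult = (np.exp(rng.normal(-0.5 * sig**2, sig, nyr))
             if sig > 0 else np.ones(nyr))
    rho, sd = config.temp_ar1_rho, config.temp_ar1_sd
    t_anom = np.zeros(nyr)
    innov = rng.normal(0.0, sd * np.sqrt(max(1.0 - rho**2, 0.0)), nyr)
    for i in range(nyr):
        t_anom[i] = (rho * t_anom[i - 1] if i else rng.normal(0.0, sd)) + innov[i]
    dt_ann = dt_trend + t_anom
    pr_ann = pr_trend * pmult

    # Month-scale anomaly noise is large: single-month GCM precipitation
    # ratios are individually erratic (hence the downstream cap at five),
    # and vapor pressure tracks the dry months so droughty summers are
    # also low-humidity ones.
    msig = config.anomaly_month_precip_sigma
    m_p = np.exp(rng.normal(-0.5 * msig**2, msig, nyr * 12))
    dt = np.repeat(dt_ann, 12) + rng.normal(0.0, config.anomaly_noise_sd, nyr * 12)
    pr = np.repeat(pr_ann, 12) * m_p
    pm_total = np.repeat(pmult, 12) * m_p
    vr = (np.exp(vpr_beta * np.repeat(dt_trend, 12))
          * pm_total ** config.vpr_precip_exp
          * np.exp(rng.normal(0.0, 0.01, nyr * 12)))
    pr = np.clip(pr, 1e-3, 5.0)
    vr = np.clip(vr, 1e-3, 5.0)

    # mild fixed spatial structure over the 2x2 lattice (exercises bilinear
    # interpolation): the SE corner warms slightly more than the NW corner.
    corner = np.array([[0.97, 1.0], [1.0, 1.03]])
    dtemp = dt[:, None, None] * corner[None]
    pratio = pr[:, None, None] * np.ones((2, 2))[None]
    vratio = vr[:, None, None] * np.ones((2, 2))[None]

    return xr.Dataset(
        {
            "dtemp": (("time", "yc", "xc"), dtemp),
            "pratio": (("time", "yc", "xc"), pratio),
            "vratio": (("time", "yc", "xc"), vratio),
        },
        coords={
            "time": np.arange(nyr * 12),
            "year": ("time", np.repeat(years, 12)),
            "month": ("time", np.tile(np.arange(1, 13), nyr)),
            "yc": np.array([0.0, max(config.ny - 1, 1)]),
            "xc": np.array([0.0, max(config.nx - 1, 1)]),
        },
        attrs={"style": style, "seed": config.seed},
    )


def generate_co2_path(year_start: int = 1895, year_end: int = 2100,
                      reference: float = 350.0, effects_off: bool = False,
                      ppm_1895: float = 294.0, ppm_2000: float = 370.0,
                      ppm_2100: float = 856.0,
                      doubling_year: int | None = None) -> pd.Series:
    """Annual atmospheric CO2 series (ppm), indexed by year.

    ``effects_off`` returns the reference concentration every year.  With
    ``doubling_year`` set, the series rises exponentially from the reference
    at ``year_start`` to exactly twice the reference at ``doubling_year``.
    Otherwise an A2-like monotone path: slow historical rise to 2000, then an
    accelerating rise to ``ppm_2100``.
    """
    years = np.arange(year_start, year_end + 1)
    if effects_off:
        return pd.Series(np.full(len(years), reference), index=years, name="co2_ppm")
    if doubling_year is not None:
        ppm = reference * 2.0 ** ((years - year_start) / (doubling_year - year_start))
        return pd.Series(ppm, index=years, name="co2_ppm")
    ppm = np.empty(len(years), float)
    hist = years <= 2000
    frac = np.clip((years[hist] - 1895) / (2000 - 1895), 0.0, None)
    ppm[hist] = ppm_1895 + (ppm_2000 - ppm_1895) * frac ** 1.8
    fut = ~hist
    ppm[fut] = ppm_2000 + (ppm_2100 - ppm_2000) * ((years[fut] - 2000) / 100.0) ** 1.6
    return pd.Series(ppm, index=years, name="co2_ppm")
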